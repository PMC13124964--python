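"""MedDRA PT -> primary SOC mapping from a user-supplied dictionary.

MedDRA itself is licensed and cannot ship with the package; analyses of
real data require the user's own two-column (pt, soc) file.  A small toy
dictionary covering the terms used by the synthetic generator is bundled
for tests and examples.  Each PT maps to exactly one primary SOC (no
multi-axial fan-out), so SOC-level counts partition PT-level counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

logger = logging.getLogger(__name__)

UNMAPPED = "UNMAPPED"
DROPPED = "dropped"


class DictionaryError(Exception):
    """Unusable PT->SOC dictionary file."""


@dataclass
class PtSocDictionary:
    """Case-insensitive PT -> primary SOC lookup table."""

    entries: dict[str, str]  # casefolded PT -> SOC
    version_label: str = ""
    display: dict[str, str] = field(default_factory=dict)  # casefolded PT -> original PT

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return pt.strip().casefold() in self.entries


def load_dictionary(path: str | Path, version_label: str | None = None) -> PtSocDictionary:
    """Load a delimited two-column (pt, soc) file, tab- or comma-separated.

    A header row ``pt<sep>soc`` is optional.  Rows that restate an existing
    PT with the same SOC merge silently (case-insensitively); a PT mapped
    to two different SOCs is a hard error naming the term.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise DictionaryError(f"cannot read dictionary file {path}: {exc}") from exc

    entries: dict[str, str] = {}
    display: dict[str, str] = {}
    conflicts: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise DictionaryError(f"{path}:{lineno}: expected two columns (pt, soc), got {line!r}")
        pt, soc = parts[0], parts[1]
        if lineno == 1 and pt.casefold() == "pt" and soc.casefold() == "soc":
            continue
        key = pt.casefold()
        if key in entries and entries[key] != soc:
            conflicts.append(display[key])
        else:
            entries[key] = soc
            display[key] = pt
    if conflicts:
        raise DictionaryError(
            f"{path}: conflicting SOC assignments for PT(s): " + ", ".join(sorted(set(conflicts)))
        )
    label = version_label if version_label is not None else path.stem
    logger.info("loaded PT->SOC dictionary %r: %d entries", label, len(entries))
    return PtSocDictionary(entries=entries, version_label=label, display=display)


def toy_dictionary_path() -> Path:
    """Path of the bundled ~37-term toy dictionary (tests and examples only)."""
    return Path(resources.files("faersig").joinpath("data/pt_soc_toy.tsv"))


def load_toy_dictionary() -> PtSocDictionary:
    return load_dictionary(toy_dictionary_path(), version_label="toy")


def soc_of(pt: str, dictionary: PtSocDictionary, policy: str = "unmapped-bucket") -> str:
    """Primary SOC of ``pt``, case-insensitively.

    Unknown PTs follow ``policy``: ``"unmapped-bucket"`` (default) pools
    them under the sentinel SOC ``UNMAPPED``; ``"drop"`` returns the
    sentinel ``dropped`` and the caller excludes the term from SOC-level
    counting (occurrences are logged).
    """
    soc = dictionary.entries.get(pt.strip().casefold())
    if soc is not None:
        return soc
    if policy == "unmapped-bucket":
        return UNMAPPED
    if policy == "drop":
        logger.debug("PT %r not in dictionary: dropped from SOC-level analysis", pt)
        return DROPPED
    raise ValueError(f"unknown unknown-PT policy: {policy!r}")
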