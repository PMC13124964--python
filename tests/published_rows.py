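"""Published FAERS disproportionality statistics for potassium citrate,
used as fixtures for the threshold / signal-rule logic.

Each row: (label, n, ror, ror_low, ror_high, prr, chi2, ic, ic025, ebgm,
ebgm05).  These are reported point estimates; the underlying background
counts are not public, so they exercise decision logic, not computation.
"""

SOC_ROWS = [
    ("Product Issues", 41, 10.00, 7.23, 13.83, 9.03, 296.32, 3.17, 2.85, 9.03, 6.54),
    ("Investigations", 96, 6.07, 4.82, 7.65, 4.79, 303.95, 2.26, 2.03, 4.79, 3.83),
    ("Renal And Urinary Disorders", 31, 5.01, 3.47, 7.24, 4.69, 91.43, 2.23, 1.85, 4.68, 3.25),
    ("Gastrointestinal Disorders", 60, 3.34, 2.54, 4.40, 2.97, 82.97, 1.57, 1.29, 2.97, 2.26),
    ("Surgical And Medical Procedures", 9, 3.21, 1.66, 6.22, 3.16, 13.39, 1.66, 0.99, 3.16, 1.63),
    ("Injury, Poisoning And Procedural Complications", 83, 2.00, 1.57, 2.55, 1.78, 32.32, 0.83, 0.59, 1.78, 1.40),
    ("Metabolism And Nutrition Disorders", 12, 1.89, 1.07, 3.37, 1.87, 4.91, 0.90, 0.31, 1.87, 1.05),
    ("General Disorders And Administration Site Conditions", 146, 1.86, 1.51, 2.28, 1.53, 35.68, 0.61, 0.42, 1.53, 1.26),
    ("Cardiac Disorders", 12, 1.79, 1.01, 3.17, 1.76, 4.02, 0.82, 0.23, 1.76, 0.99),
]

PT_ROWS = [
    ("Product residue present", 67, 695.34, 533.26, 906.68, 573.23, 37720.8, 9.14, 8.88, 564.81, 434.94),
    ("Medication residue present", 16, 177.69, 107.59, 293.46, 170.27, 2681.17, 7.41, 6.89, 169.52, 102.69),
    ("Product solubility abnormal", 13, 128.36, 73.76, 223.38, 124.01, 1581.65, 6.95, 6.38, 123.62, 71.06),
    ("Foreign body in respiratory tract", 4, 109.93, 40.99, 294.85, 108.79, 426.03, 6.76, 5.75, 108.49, 40.45),
    ("Foreign body", 4, 66.28, 24.72, 177.66, 65.59, 254.03, 6.03, 5.03, 65.48, 24.43),
    ("Malabsorption", 4, 30.68, 11.45, 82.19, 30.36, 113.54, 4.92, 3.92, 30.34, 11.33),
    ("Flank pain", 4, 25.87, 9.66, 69.31, 25.6, 94.56, 4.68, 3.67, 25.59, 9.55),
    ("Product use complaint", 8, 24.89, 12.36, 50.16, 24.39, 179.51, 4.61, 3.89, 24.38, 12.10),
    ("Proteinuria", 7, 21.37, 10.11, 45.14, 20.99, 133.32, 4.39, 3.63, 20.98, 9.93),
    ("Poor quality product administered", 4, 18.77, 7.01, 50.27, 18.58, 66.54, 4.22, 3.21, 18.57, 6.93),
    ("Product physical issue", 8, 18.42, 9.14, 37.11, 18.05, 128.94, 4.17, 3.46, 18.04, 8.96),
    ("Product substitution issue", 13, 12.51, 7.20, 21.76, 12.12, 132.98, 3.60, 3.03, 12.12, 6.97),
    ("Retching", 4, 11.02, 4.11, 29.51, 10.91, 36.03, 3.45, 2.44, 10.91, 4.07),
    ("Product dispensing error", 5, 10.47, 4.33, 25.30, 10.34, 42.24, 3.37, 2.47, 10.34, 4.28),
    ("Pollakiuria", 4, 5.58, 2.08, 14.96, 5.53, 14.89, 2.47, 1.46, 5.54, 2.07),
    ("Throat irritation", 4, 5.12, 1.91, 13.72, 5.07, 13.12, 2.34, 1.34, 5.08, 1.90),
    ("Drug ineffective", 99, 4.83, 3.84, 6.07, 3.83, 222.5, 1.94, 1.71, 3.83, 3.07),
    ("Drug ineffective for unapproved indication", 5, 4.16, 1.72, 10.06, 4.12, 11.86, 2.04, 1.14, 4.12, 1.71),
    ("Blood creatinine increased", 4, 3.87, 1.44, 10.35, 3.83, 8.40, 1.94, 0.93, 3.84, 1.43),
    ("Abdominal discomfort", 12, 3.75, 2.11, 6.67, 3.66, 23.45, 1.87, 1.29, 3.66, 2.06),
    ("Dysphagia", 6, 3.74, 1.67, 8.38, 3.69, 11.86, 1.89, 1.06, 3.70, 1.65),
    ("Oropharyngeal pain", 6, 3.49, 1.56, 7.81, 3.44, 10.46, 1.78, 0.96, 3.45, 1.54),
    ("Maternal exposure during pregnancy", 5, 2.76, 1.14, 6.68, 2.74, 5.55, 1.45, 0.55, 2.74, 1.13),
    ("Drug dose omission", 8, 2.35, 1.16, 4.72, 2.31, 6.04, 1.21, 0.50, 2.32, 1.15),
    ("Abdominal pain", 8, 2.05, 1.02, 4.12, 2.02, 4.19, 1.02, 0.30, 2.02, 1.01),
    ("Rash", 15, 1.94, 1.16, 3.25, 1.89, 6.52, 0.93, 0.40, 1.90, 1.13),
]


def as_statistics(row, level):
    from faersig.stats import SignalStatistics

    (label, n, ror, low, high, prr, chi2, ic, ic025, ebgm, ebgm05) = row
    return SignalStatistics(
        event_label=label, level=level, a=n,
        ror=ror, ror_low=low, ror_high=high,
        prr=prr, chi2=chi2, ic=ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05,
    )
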