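pt	soc
Product residue present	Product issues
Medication residue present	Product issues
Product solubility abnormal	Product issues
Product physical issue	Product issues
Product use complaint	Product issues
Product substitution issue	Product issues
Poor quality product administered	Product issues
Product dispensing error	Injury, poisoning and procedural complications
Drug dose omission	Injury, poisoning and procedural complications
Maternal exposure during pregnancy	Injury, poisoning and procedural complications
Foreign body	Injury, poisoning and procedural complications
Foreign body in respiratory tract	Injury, poisoning and procedural complications
Drug ineffective	General disorders and administration site conditions
Drug ineffective for unapproved indication	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Pyrexia	General disorders and administration site conditions
Blood creatinine increased	Investigations
Blood potassium increased	Investigations
Weight decreased	Investigations
Pollakiuria	Renal and urinary disorders
Proteinuria	Renal and urinary disorders
Nephrolithiasis	Renal and urinary disorders
Renal colic	Renal and urinary disorders
Abdominal pain	Gastrointestinal disorders
Abdominal discomfort	Gastrointestinal disorders
Dysphagia	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Retching	Gastrointestinal disorders
Malabsorption	Gastrointestinal disorders
Rash	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Palpitations	Cardiac disorders
Hyperkalaemia	Metabolism and nutrition disorders
Throat irritation	Respiratory, thoracic and mediastinal disorders
Oropharyngeal pain	Respiratory, thoracic and mediastinal disorders
Flank pain	Musculoskeletal and connective tissue disorders
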