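pt,soc
Dissociation,Psychiatric disorders
Dissociative disorder,Psychiatric disorders
Flashback,Psychiatric disorders
Morbid thoughts,Psychiatric disorders
Derealization,Psychiatric disorders
Autoscopy,Psychiatric disorders
Euphoric mood,Psychiatric disorders
Suicidal ideation,Psychiatric disorders
Major depression,Psychiatric disorders
Delusional perception,Psychiatric disorders
Illusion,Psychiatric disorders
Depressive symptom,Psychiatric disorders
Suicide threat,Psychiatric disorders
Conversion disorder,Psychiatric disorders
Feeling guilty,Psychiatric disorders
Negative thoughts,Psychiatric disorders
Self-injurious ideation,Psychiatric disorders
Flat affect,Psychiatric disorders
Dysphoria,Psychiatric disorders
Feelings of worthlessness,Psychiatric disorders
Panic attack,Psychiatric disorders
Suicide attempt,Psychiatric disorders
Agoraphobia,Psychiatric disorders
Bipolar I disorder,Psychiatric disorders
Panic disorder,Psychiatric disorders
Disturbance in social behavior,Psychiatric disorders
Alcohol abuse,Psychiatric disorders
Feeling of despair,Psychiatric disorders
Logorrhea,Psychiatric disorders
Hypomania,Psychiatric disorders
Inappropriate affect,Psychiatric disorders
Somatic symptom disorder,Psychiatric disorders
Depersonalisation/derealisation disorder,Psychiatric disorders
Depression,Psychiatric disorders
Depression suicidal,Psychiatric disorders
Anxiety,Psychiatric disorders
Insomnia,Psychiatric disorders
Agitation,Psychiatric disorders
Irritability,Psychiatric disorders
Hallucination,Psychiatric disorders
Sedation,Nervous system disorders
Impaired hand-eye coordination,Nervous system disorders
Psychogenic seizure,Nervous system disorders
Essential tremor,Nervous system disorders
Dizziness,Nervous system disorders
Headache,Nervous system disorders
Somnolence,Nervous system disorders
Paraesthesia,Nervous system disorders
Tremor,Nervous system disorders
Hypoaesthesia,Nervous system disorders
Dysgeusia,Nervous system disorders
Abdominoplasty,Surgical and medical procedures
Hospitalisation,Surgical and medical procedures
Tachyphylaxis,General disorders and administration site conditions
Feeling drunk,General disorders and administration site conditions
Feeling of relaxation,General disorders and administration site conditions
Therapeutic response increase,General disorders and administration site conditions
Therapeutic product effect increase,General disorders and administration site conditions
Fatigue,General disorders and administration site conditions
Drug ineffective,General disorders and administration site conditions
Feeling abnormal,General disorders and administration site conditions
Malaise,General disorders and administration site conditions
"Drug-monitoring procedure incorrectly performed","Injury, poisoning, and procedural complications"
"Alcohol poisoning","Injury, poisoning, and procedural complications"
"Product use issue","Injury, poisoning, and procedural complications"
"Fall","Injury, poisoning, and procedural complications"
"Nasal discomfort","Respiratory, thoracic, and mediastinal disorders"
"Throat irritation","Respiratory, thoracic, and mediastinal disorders"
"Epistaxis","Respiratory, thoracic, and mediastinal disorders"
"Dyspnoea","Respiratory, thoracic, and mediastinal disorders"
Cystitis interstitial,Renal and urinary disorders
Pollakiuria,Renal and urinary disorders
Hyperacusis,Ear and labyrinth disorders
Tinnitus,Ear and labyrinth disorders
Nausea,Gastrointestinal disorders
Vomiting,Gastrointestinal disorders
Diarrhoea,Gastrointestinal disorders
Blood pressure increased,Investigations
Heart rate increased,Investigations
Weight increased,Investigations
Hypertension,Vascular disorders
Hot flush,Vascular disorders
Flushing,Vascular disorders
Device malfunction,Product issues
Product dose omission issue,Product issues
Nasopharyngitis,Infections and infestations
Urinary tract infection,Infections and infestations
Vision blurred,Eye disorders
Diplopia,Eye disorders
Palpitations,Cardiac disorders
Tachycardia,Cardiac disorders
Arthralgia,Musculoskeletal and connective tissue disorders
Myalgia,Musculoskeletal and connective tissue disorders
Rash,Skin and subcutaneous tissue disorders
Hyperhidrosis,Skin and subcutaneous tissue disorders
Decreased appetite,Metabolism and nutrition disorders
Dehydration,Metabolism and nutrition disorders
Hypersensitivity,Immune system disorders
"Neoplasm malignant","Benign, malignant, and unspecified neoplasms (including cysts and polyps)"
Alcohol use,Social circumstances
Hepatic function abnormal,Hepatobiliary disorders
"Abortion spontaneous","Pregnancy, puerperium, and perinatal conditions"
Hypothyroidism,Endocrine disorders
Erectile dysfunction,Reproductive system and breast disorders
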