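adr_name	icd10_code
Valvular Heart Disease	I08.8
Rheumatic Carditis	I09.9
Myocardial Infarction	I21
Myocardial Ischemia	I25.6
Heart Disease	I30-I52
Constrictive Pericarditis	I31.1
Pericardial Effusion	I31.3
Cardiac Tamponade	I31.9
Pericarditis	I32.8
Endocarditis	I39.8
Myocarditis	I40.8
Cardiomyopathy	I42
Second Degree Heart Block	I44.1
Complete Heart Block	I44.2
Heart Block	I45.5
Cardiac Arrest	I46
Sinus Tachycardia	I47
Tachycardia	I47
Junctional Tachycardia	I47.1
Multifocal Atrial Tachycardia	I47.1
Nodal Tachycardia	I47.1
Supraventricular Tachycardia	I47.1
Paroxysmal Ventricular Tachycardia	I47.2
Ventricular Tachycardia	I47.2
Heart Failure	I50
Congestive Heart Failure	I50.0
Right Heart Failure	I50.0
Cardiomegaly	I51.7
Cardiac Abnormality	I97.1
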