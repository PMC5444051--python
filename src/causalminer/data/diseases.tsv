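disease_id	preferred_name	synonyms	category
D000236	Adenoma	adenoma|adenomas	Neoplasms
D000783	Aneurysm	aneurysm|aneurysms	Cardiovascular Diseases
D001766	Blindness	blindness	Eye Diseases
D002386	Cataract	cataract|cataracts	Eye Diseases
D005901	Glaucoma	glaucoma	Eye Diseases
D006333	Heart Failure	heart failure|cardiac failure	Cardiovascular Diseases
D006470	Hemorrhage	hemorrhage|haemorrhage|bleeding	Pathological Conditions
D006505	Hepatitis	hepatitis	Digestive System Diseases
D006509	Hepatitis B	hepatitis B|hepatitis B virus infection	Virus Diseases
D006526	Hepatitis C	hepatitis C|hepatitis C virus infection	Virus Diseases
D006528	Carcinoma, Hepatocellular	hepatocellular carcinoma|hepatoma|HCC	Neoplasms
D007238	Infarction	infarction|infarct	Pathological Conditions
D008103	Liver Cirrhosis	liver cirrhosis|cirrhosis of the liver|hepatic cirrhosis	Digestive System Diseases
D008107	Liver Diseases	liver diseases|liver disease	Digestive System Diseases
D008581	Meningitis	meningitis	Nervous System Diseases
D009203	Myocardial Infarction	myocardial infarction|heart attack	Cardiovascular Diseases
D011014	Pneumonia	pneumonia	Respiratory Tract Diseases
D012004	Rectal Neoplasms	rectal neoplasms|rectal cancer|rectal tumor	Neoplasms
D013345	Subarachnoid Hemorrhage	subarachnoid hemorrhage|subarachnoid haemorrhage	Cardiovascular Diseases
D013927	Thrombosis	thrombosis|thrombus	Cardiovascular Diseases
D020521	Stroke	stroke|cerebrovascular accident	Nervous System Diseases
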