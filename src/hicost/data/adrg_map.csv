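prefix,category,system
J06,upper respiratory disease,ADRG
J39,upper respiratory disease,ADRG
J13,respiratory infection/inflammation,ADRG
J14,respiratory infection/inflammation,ADRG
J15,respiratory infection/inflammation,ADRG
J18,respiratory infection/inflammation,ADRG
J44,chronic obstructive airway disease,ADRG
J45,asthma and asthmatic bronchitis,ADRG
J46,asthma and asthmatic bronchitis,ADRG
I50,heart failure and shock,ADRG
I10,hypertension,ADRG
I20,angina pectoris,ADRG
I25,coronary atherosclerosis/thrombus/occlusion,ADRG
I63,cerebral ischemic disease,ADRG
I65,cerebral ischemic disease,ADRG
I66,cerebral ischemic disease,ADRG
I69,sequela of cerebrovascular disease,ADRG
I61,intracranial haemorrhage,ADRG
I62,intracranial haemorrhage,ADRG
R42,other neurological disorders,ADRG
I67,other neurological disorders,ADRG
R51,headache,ADRG
R07,chest pain,ADRG
I47,arrhythmia and conduction disorder,ADRG
I48,arrhythmia and conduction disorder,ADRG
I49,arrhythmia and conduction disorder,ADRG
E78,hyperlipidemia,ADRG
E10,diabetes,ADRG
E11,diabetes,ADRG
C16,digestive system malignant tumour,ADRG
C18,digestive system malignant tumour,ADRG
C22,digestive system malignant tumour,ADRG
C34,respiratory system tumour,ADRG
Z51,radiotherapy for malignant proliferative diseases,ADRG
N20,"urinary calculi, obstruction, and urethral stricture",ADRG
N21,"urinary calculi, obstruction, and urethral stricture",ADRG
N28,other diseases of kidney and urinary system,ADRG
N18,renal insufficiency,ADRG
N19,renal insufficiency,ADRG
N39,renal and urinary tract infection,ADRG
N10,renal and urinary tract infection,ADRG
K35,other digestive system diagnosis,ADRG
K40,other digestive system diagnosis,ADRG
K64,other digestive system diagnosis,ADRG
K56,obstruction of digestive tract or abdominal pain,ADRG
R10,obstruction of digestive tract or abdominal pain,ADRG
K20,"esophagitis, gastroenteritis",ADRG
K29,"esophagitis, gastroenteritis",ADRG
A09,"esophagitis, gastroenteritis",ADRG
K80,other diseases of biliary tract,ADRG
K81,acute biliary tract disease,ADRG
K83,other diseases of biliary tract,ADRG
K70,liver disease,ADRG
K74,liver disease,ADRG
B18,liver disease,ADRG
N40,other male reproductive system disorders,ADRG
N70,female reproductive infection,ADRG
N76,female reproductive infection,ADRG
D25,other diseases of female reproductive system,ADRG
N83,other diseases of female reproductive system,ADRG
N60,benign breast lesions,ADRG
N63,benign breast lesions,ADRG
H25,cataract of various types,ADRG
H26,cataract of various types,ADRG
H33,other eye diseases,ADRG
H35,other eye diseases,ADRG
S06,"injury except forearm, wrist, hand and foot",ADRG
S22,"injury except forearm, wrist, hand and foot",ADRG
S32,"injury except forearm, wrist, hand and foot",ADRG
S42,"injury except forearm, wrist, hand and foot",ADRG
S72,"injury except forearm, wrist, hand and foot",ADRG
S82,"injury except forearm, wrist, hand and foot",ADRG
M54,neck and back disease,ADRG
M51,neck and back disease,ADRG
M50,neck and back disease,ADRG
M62,"other bones, muscles, tendons, connective tissue",ADRG
M79,"other bones, muscles, tendons, connective tissue",ADRG
M15,osteopathy and other joint diseases,ADRG
M16,osteopathy and other joint diseases,ADRG
M17,osteopathy and other joint diseases,ADRG
I83,venous disease,ADRG
E04,endocrine disorders,ADRG
E05,endocrine disorders,ADRG
D10,"head, neck, ear, nose, pharynx and mouth non-malignant proliferative",ADRG
D11,"head, neck, ear, nose, pharynx and mouth non-malignant proliferative",ADRG
J33,"head, neck, ear, nose, pharynx and mouth non-malignant proliferative",ADRG
K02,oral and dental related diseases,ADRG
K04,oral and dental related diseases,ADRG
L20,inflammatory dermatosis,ADRG
L30,inflammatory dermatosis,ADRG
L02,major skin disorders,ADRG
B02,major skin disorders,ADRG
F20,schizophrenia,ADRG
Z50,other rehabilitation treatment,ADRG
R50,fever with unknown cause,ADRG
H81,imbalance and hearing disorders,ADRG
H93,imbalance and hearing disorders,ADRG
J02,upper respiratory tract infection and tympanitis,ADRG
H66,upper respiratory tract infection and tympanitis,ADRG
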