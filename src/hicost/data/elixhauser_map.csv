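prefix,category,system
J41,chronic pulmonary disease,Elixhauser
J42,chronic pulmonary disease,Elixhauser
J43,chronic pulmonary disease,Elixhauser
J44,chronic pulmonary disease,Elixhauser
J45,chronic pulmonary disease,Elixhauser
J47,chronic pulmonary disease,Elixhauser
I10,"hypertension, uncomplicated",Elixhauser
E11,"diabetes, uncomplicated",Elixhauser
E10,"diabetes, complicated",Elixhauser
I50,congestive heart failure,Elixhauser
C16,solid tumour without metastasis,Elixhauser
C18,solid tumour without metastasis,Elixhauser
C22,solid tumour without metastasis,Elixhauser
C34,solid tumour without metastasis,Elixhauser
C50,solid tumour without metastasis,Elixhauser
C61,solid tumour without metastasis,Elixhauser
F20,psychoses,Elixhauser
F29,psychoses,Elixhauser
F32,depression,Elixhauser
F33,depression,Elixhauser
K70,liver disease,Elixhauser
K74,liver disease,Elixhauser
B18,liver disease,Elixhauser
K25,peptic ulcer disease excluding bleeding,Elixhauser
K26,peptic ulcer disease excluding bleeding,Elixhauser
K27,peptic ulcer disease excluding bleeding,Elixhauser
N18,renal failure,Elixhauser
N19,renal failure,Elixhauser
M05,rheumatoid arthritis/collagen vascular diseases,Elixhauser
M06,rheumatoid arthritis/collagen vascular diseases,Elixhauser
I47,cardiac arrhythmias,Elixhauser
I48,cardiac arrhythmias,Elixhauser
I49,cardiac arrhythmias,Elixhauser
E03,hypothyroidism,Elixhauser
E66,obesity,Elixhauser
G40,other neurological disorders,Elixhauser
G20,other neurological disorders,Elixhauser
I69,other neurological disorders,Elixhauser
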