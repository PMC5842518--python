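name,category,sensitivity,ic50_gefitinib_nM,ic50_erlotinib_nM
delE746_A750,Del 19,high,,
delL747_P753insS,Del 19,high,,
delL747_T751,Del 19,high,,
delL747_A750insP,Del 19,high,,
delL747_S752,Del 19,high,,
delE746_S752insV,Del 19,high,306,14
delE746_P753insVS,Del 19,high,,
delL747_T751insP,Del 19,high,,
delE746_T751insA,Del 19,high,,
delL747_P753,Del 19,high,,
delS752_I759,Del 19,high,,
L858R,L858R,high,,
E709A,E709X,moderate,,
E709K,E709X,moderate,,
delE709_T710insD,Del 18,moderate,,
G719A,G719X,moderate,,
G719C,G719X,moderate,,
G719S,G719X,moderate,,
I744_K745insKIPVAI,Ins 19,moderate,,
S768I,S768I,moderate,,
L861Q,L861Q,moderate,,
A763_Y764insFQEA,Ins 20,moderate,,
V769_D770insASV,Ins 20,low,,
D770_N771insSVD,Ins 20,low,,
H773_V774insH,Ins 20,low,,
H773_V774insPH,Ins 20,low,,
H773_V774insNPH,Ins 20,low,,
T790M,T790M,low,,
T790M_L858R,T790M,low,,
T790M_delE746_A750,T790M,low,,
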