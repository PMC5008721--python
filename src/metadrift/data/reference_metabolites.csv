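name,formula,adducts,expected_rt,cvr_flag
Alanine,C3H7NO2,[M+H]+,12.20,True
Choline,C5H13NO,[M+H]+,10.06,True
Leucine/Isoleucine,C6H13NO2,[M+H]+,9.45,True
Lysine,C6H14N2O2,[M-H]-,13.02,False
Oxovaleric acid,C5H8O3,[M-H]-,9.90,False
Pentoses,C5H10O5,[M-H]-,9.96,False
Phenylalanine,C9H11NO2,[M+H]+,9.74,True
Tyrosine,C9H11NO3,[M+H]+,11.62,True
Uridine,C9H12N2O6,[M-H]-,7.20,False
Valine,C5H11NO2,[M-H]-,10.19,True
Glutamine,C5H10N2O3,[M+H]+,13.63,False
Glycine,C2H5NO2,[M+H]+,14.20,False
Hydroxydecanoic acid,C10H20O3,[M-H]-,9.45,False
Indoxyl sulphate,C8H7NO4S,[M-H]-,9.13,True
PC C40:7,C48H82NO8P,[M+H]+,5.14,False
Trimethylamine-N-oxide,C3H9NO,[M+H]+,11.88,True
Creatine,C4H9N3O2,[M+H]+,12.19,False
LysoPC C16:1,C24H48NO7P,[M+H]+,4.83,False
LysoPC C18:2,C26H50NO7P,[M+H]+,5.13,False
Ornithine,C5H12N2O2,[M-H]-,12.54,True
PC C34:3,C42H78NO8P,[M+H]+,5.27,False
PC C36:5,C44H78NO8P,[M+H]+,5.01,False
PC C36:6,C44H76NO8P,[M+H]+,4.61,False
Sarcosine,C3H7NO2,[M-H]-,11.27,False
Tryptophan,C11H12N2O2,[M+H]+,9.83,False
Uracil,C4H4N2O2,[M+H]+,6.98,False
Acetylglycine,C4H7NO3,[M-H]-,12.97,False
Arginine,C6H14N4O2,[M+H]+,12.15,False
Carnitine,C7H15NO3,[M+H]+,10.88,False
Hydroxyisobutyric acid,C4H8O3,[M-H]-,12.10,False
Leucyl-proline,C11H20N2O3,[M+H]+,9.19,False
LysoPE C20:4,C25H44NO7P,[M+H]+,8.27,False
Pantothenic acid,C9H17NO5,[M-H]-,12.69,False
PC C38:6,C46H80NO8P,[M+H]+,5.21,False
Pyroglutamic acid,C5H7NO3,[M-H]-,12.89,False
Threonine,C4H9NO3,[M+H]+,13.11,False
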