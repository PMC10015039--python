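raw_label,ctu
Magdalenian,Magdalenian
Early Magdalenian,Magdalenian
Middle Magdalenian,Magdalenian
Late Magdalenian,Magdalenian
Final Magdalenian,Magdalenian
Terminal Magdalenian,Magdalenian
Cresswellian,Magdalenian
Hamburgian,Magdalenian
Havelte,Magdalenian
Epigravettian,Epigravettian
Early Epigravettian,Epigravettian
Late Epigravettian,Epigravettian
Romanellian,Epigravettian
Bouverian,Epigravettian
Azilian,ABC
Federmessergroups,ABC
Federmesser,ABC
Arch-Backed Complex,ABC
ABC,ABC
Ahrensburgian,TPC
Epiahrensburgian,TPC
Bromme,TPC
Swiderian,TPC
Tanged Point Complex,TPC
TPC,TPC
Belloisian,BBT
Long Blade Industry,BBT
Laborian,BBT
BBT,BBT
Mesolithic,Mesolithic
Early Mesolithic,Mesolithic
Epipalaeolithic,Mesolithic
Beuronian,Mesolithic
Maglemose,Mesolithic
Sauveterrian,Mesolithic
Microlaminar Epipalaeolithic,Mesolithic
Gravettian,
Solutrean,
Aurignacian,
Mousterian,
Unknown,
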