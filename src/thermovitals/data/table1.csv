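species,taxa,immobilized_or_voluntary,color,integument_thick,subcutaneous_fat,quality_score,true_rr,irt_rr,rr_location,true_hr,irt_hr,hr_location,true_measured,transcription_notes
African crested porcupine,mammal,voluntary,gray,thick,no,4,,,,120,,,yes,"uncertain: run-together digits '4120' read as quality 4 + true HR 120; could be true RR 12; either reading leaves membership and success flags unchanged"
Andean bear,mammal,immobilized,black,thick,no,5,,,,40,42,inner leg,yes,
Barn owl,bird,voluntary,tan,thick,no,5,,,,,,,no,
Bat-eared fox,mammal,voluntary,brown,thick,no,4,,,,,,,no,
Blue penguin,bird,voluntary,"black, white",thick,yes,4,,,,,,,yes,"listed among failed validations, so a true measurement existed; its value is not recoverable from the source table"
Bonobo,mammal,voluntary,black,thin,no,7,22,20,"nostrils, chest",82,77.4,"chest, palm",yes,
Brown bear,mammal,voluntary,dark brown,thick,yes,6,,12,,,60,,no,"IRT-only values from the companion no-true-comparison table; no reference measurement"
California sea lion,mammal,voluntary,gray,thin,yes,6,18,20,"nostrils, abdomen",,,,yes,
Central American tapir,mammal,voluntary,"black, white",thin,no,5,,,,,,,no,
Cheetah,mammal,immobilized,tan,thin,no,7,16,15,"abdomen, chest",80,84,inner leg,yes,
Chuckwalla,reptile,voluntary,gray,thick,no,7,22,23,abdomen,,,,yes,
Dabb spiny tailed lizard,reptile,voluntary,gray,thick,no,5,21,24,"neck, nostrils",,,,yes,
Domestic cat,mammal,immobilized,white,thick,no,8,43,44,abdomen,116,112.5,stomach,yes,
Dromedary camel,mammal,voluntary,tan,thin,no,6,10,12,chest,,,,yes,
Eastern bongo,mammal,voluntary,tan,thin,no,8,29,31,abdomen,71,70.2,inner leg,yes,
Emu,bird,voluntary,brown,thin,no,6,11,7,nostrils,40,42,face,yes,
Gopher tortoise,reptile,voluntary,gray,thick,no,5,,24,,,,,no,"uncertain: run-together digits '524' read as quality 5 + IRT RR 24 with no true value (reference measurement prevented by thick scales)"
Gorilla (immobilized),mammal,immobilized,black,thin,no,7,18,20,"nostrils, chest",80,77.4,"ear, chest, palm",yes,
Gorilla (voluntary),mammal,voluntary,black,thin,no,5,18,18,"nostrils, chest",86,91,"hand, chest",yes,
Gray seal,mammal,voluntary,gray,thin,yes,6,40,38,mouth,103,98.4,face,yes,
Gray woolly monkey,mammal,voluntary,brown,thick,no,8,29,29,chest,172,175.8,"chest, palm",yes,
Harbor seal,mammal,voluntary,gray,thin,yes,6,14,15,nostrils,,,,yes,
Hippopotamus,mammal,voluntary,gray,thick,yes,5,,,,,,,no,
King penguin,bird,voluntary,"black, white",thick,yes,4,,,,,,,yes,"listed among failed validations, so a true measurement existed; its value is not recoverable from the source table"
Lace monitor 1,reptile,voluntary,"black, yellow",thick,no,6,44,45,neck,,,,yes,
Lace monitor 2,reptile,voluntary,"black, yellow",thick,no,6,32,35,neck,,,,yes,
Large-spotted genet,mammal,immobilized,tan,thin,no,6,18,18,abdomen,138,134,stomach,yes,
Lesser kudu,mammal,immobilized,tan,thin,no,4,21,19,abdomen,,84.6,,yes,"IRT HR 84.6 from the companion no-true-comparison table; stethoscope placement through the enclosure failed"
Lesser Madagascar hedgehog tenrec,mammal,immobilized,pink,thin,no,7,24,24,chest,108,105.6,stomach,yes,
Linne's two toed sloth,mammal,voluntary,"tan, black",thick,no,8,31,35,nostrils,77,77.4,face,yes,
Lion 1,mammal,immobilized,tan,thin,no,5,16,15,"abdomen, chest",60,,,yes,
Lion 2,mammal,immobilized,tan,thin,no,5,15,17,"abdomen, chest",68,,,yes,
Long-tailed chinchilla,mammal,voluntary,gray,thick,no,5,37,49,nostrils,170,,,yes,
Magellanic penguin,bird,voluntary,"black, white",thick,yes,4,,,,,,,yes,"listed among failed validations, so a true measurement existed; its value is not recoverable from the source table"
Masai giraffe,mammal,voluntary,tan,thin,no,6,37,35,abdomen,52,49,inner leg,yes,
Minilop rabbit,mammal,voluntary,light brown,thick,no,5,41,42,nostrils,219,,,yes,
Orangutan,mammal,voluntary,orange,thin,no,7,25,23,"nostrils, chest",102,105.6,"chest, palm",yes,
Plains zebra,mammal,immobilized,"black, white",thin,no,8,19,14,abdomen,43,42,inner leg,yes,
Polar bear 1,mammal,immobilized,white,thick,yes,8,12,10,"abdomen, chest",46,42,"groin, snout",yes,
Polar bear 2,mammal,immobilized,white,thick,yes,7,6,7,abdomen,44,49,"groin, mouth",yes,
Prehensile-tailed porcupine,mammal,voluntary,gray,thick,no,5,,,,111,,,yes,"uncertain: run-together digits '5111' read as quality 5 + true HR 111; could be true RR 11; either reading leaves membership and success flags unchanged"
Radiated tortoise,reptile,voluntary,tan,thick,no,4,,,,,,,no,
Red footed tortoise,reptile,voluntary,gray,thick,no,6,80,78,neck,,,,yes,
Red-necked wallaby,mammal,immobilized,light brown,thin,no,7,20,20,chest,108,105.6,ear,yes,
Red panda,mammal,voluntary,black,thick,no,7,,,,118,119,inner leg,yes,
Red river hog,mammal,voluntary,red,thin,yes,4,,,,,,,no,
Screaming hairy armadillo 1,mammal,voluntary,tan,thick,no,5,,,,,,,no,
Screaming hairy armadillo 2,mammal,voluntary,tan,thick,no,5,,,,,,,no,
Slender-tailed meerkat,mammal,immobilized,"tan, black",thin,no,5,,,,146,,,yes,"uncertain: run-together digits '5146' read as quality 5 + true HR 146; could be true RR 14; either reading leaves membership and success flags unchanged"
Southern rockhopper penguin,bird,immobilized,"black, white",thick,yes,6,8,7,abdomen,,,,yes,
Southern tamandua,mammal,voluntary,"black, white",thin,no,6,,,,,,,no,
Southern three banded armadillo,mammal,voluntary,tan,thick,no,5,,,,,,,no,
Tawny frogmouth 1,bird,voluntary,brown,thick,no,6,25.6,26,nostrils,185,133.2,eye,yes,"hr_outlier: the 51.8 bpm bird error singled out in the source; excluded in the no-outlier error variant"
Tawny frogmouth 2,bird,voluntary,brown,thick,no,5,,,,,,,no,
Virginia opossum,mammal,voluntary,gray,thick,no,5,,,,,,,no,
White-bearded wildebeest,mammal,immobilized,brown,thin,no,6,2,5,chest,71,70.2,inner leg,yes,"uncertain: run-together digits '625chest' read as quality 6 + true RR 2 + IRT RR 5; biologically implausible for a wildebeest but the only reading consistent with the published error summary and group margins"
White-faced Saki monkey,mammal,immobilized,black,thin,no,8,15,15,chest,103,106,face,yes,
Yellow-backed duiker,mammal,immobilized,dark brown,thin,no,6,12,10,abdomen,72,,,yes,
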