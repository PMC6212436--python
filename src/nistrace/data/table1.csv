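species,region,native_range,vector,n,pct,NH,Hd,pi,natives,cargo_pct,distance,lat_crosses
Magallana gigas,BB,NW Pacific,Aquaculture,45,6.7,21,0.697,0.011,14.5,8.32,12.3,
Botrylloides violaceus,BB,NW Pacific,Aquaculture,4,0.60,3,0.833,0.013,20,8.32,12.3,
Austrominius modestus,BB,New Zealand-Australia,Ships,15,2.24,9,0.981,0.012,9.75,14.45,13.85,
Ficopomatus enigmaticus,BB,Australia,Ships,54,8.05,1,0,0,10.5,14.45,9.56,
Microcosmus squamiger,BB,Australia,Ships,4,0.60,2,0.5,0.001,17.3,14.45,10.7,
Xenostrobus securis,BB,New Zealand-Australia,Ships,53,7.90,42,0.987,0.054,6,14.45,13.85,
Livoneca redmanii,BB,NW Atlantic,Ships,5,0.75,1,0,0,18,5.76,4.9,
Amphibalanus eburneus,BB,NW Atlantic,Ships,4,0.60,1,0,0,6,28.49,4.9,
Mytilus trossulus,BB,"N Atlantic, N Pacific",Ships,13,1.94,6,0.641,0.034,17,12.23,1.9,
Amphibalanus amphitrites,BB,Cryptogenic,Ships,5,0.75,1,0,0,11.5,,,
Amathia verticillata,BB,Cryptogenic,Ships,7,1.04,2,0.286,0.001,18,,,
Watersipora subatra,BB,Cryptogenic,Ships,11,1.64,5,0.855,0.031,18.67,,,
Bugula neritina,BB,Cryptogenic,Aquaculture,6,0.89,1,0,0,18,,,
Mytilaster minimus,BB,Cryptogenic,Ships,21,3.13,19,0.936,0.007,16.4,,,
Callyspongia siphonella,BB,Red Sea,Ships,1,0.14,1,0,0,17,1.43,3.5,
Polydora triglanda,BB,NW Pacific,Ships,1,0.14,1,0,0,16,8.32,,
Styela clava,BB,NW Pacific,Ships,1,0.14,1,0,0,19,8.32,12.3,
Styela plicata,BB,Cryptogenic,Ships,3,0.44,1,0,0,18,,,
Magallana gigas,GL,NW Pacific,Aquaculture,4,2.45,3,0.833,0.011,21,16.69,10.5,
Ficopomatus enigmaticus,GL,Australia,Ships,35,21.5,1,0,0,4,4.50,9.14,
Styela plicata,GL,Cryptogenic,Ships,4,2.45,4,1,0.042,21,,,
Aiptasia pulchella,GL,Cryptogenic,Ships,1,0.7,1,0,0,21,,,
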