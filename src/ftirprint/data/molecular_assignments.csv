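comparison,wavenumber,assignment,reference
NEE and NWE,1736,C=O stretching [lipids],CR65
NEE and NWE,1643,C=O stretching [Amide I],CR65
NEE and NWE,1605,v_as (COO-) [polysaccharides pectin],CR65
NEE and NWE,1546,Amide II: [protein N-H bending C-N stretching] alpha-helical structure,CR89
NEE and NWE,1466,CH2 bending in lipid,CR50
NEE and NWE,1446,aromatic ring stretch vibrations tannins,CR61
NEE and NWE,1405,CH3 asymmetric deformation,CR65
NEE and NWE,1385,Ring stretching vibrations mixed strongly with CH in-plane bending,CR65
NEE and NWE,1158,vC-O of proteins and carbohydrates,CR65
NEE and NWE,1034,C-O stretch tannins,CR61
NEE and NWE,1015,nu (CO) nu (CC) delta (OCH) ring in pectin,CR50
NEE and NWE,964,C-O deoxyribose C-C,CR65
NEE and WS,1725,C=O stretching band mode of the fatty acid ester,CR65
NEE and WS,1662,Amide I or fatty acid esters,CR65
NEE and WS,1648,Amide I,CR65
NEE and WS,1608,aromatic ring stretch vibrations tannins,CR61
NEE and WS,1586,Amide II,CR65
NEE and WS,1542,Amide II,CR90
NEE and WS,1531,Amide II,CR91
NEE and WS,1446,aromatic ring stretch vibrations tannins,CR61
NEE and WS,1530,C=N adenine cytosine,CR65
NEE and WS,1014,phosphodiester stretching bands [symmetrical and asymmetrical],CR65
NWE and WS,1725,C=O stretching band mode of the fatty acid ester,CR65
NWE and WS,1678,Stretching C=O vibrations that are H-bonded,CR65
NWE and WS,1662,Amide I or fatty acid esters,CR65
NWE and WS,1445,lipids,CR63
NWE and WS,1397,CH3 symmetric deformation,CR65
SRC and others,1748,C=O stretching vibration of alkyl ester pectin,CR62
SRC and others,1728,nu (C=O) ester cutin,CR62
SRC and others,1678,Stretching C=O vibrations that are H-bonded,CR65
SRC and others,1651,phenolic compounds/cutan [aromatic and C=C functional groups],CR62
SRC and others,1608,aromatic ring stretch vibrations tannins,CR61
SRC and others,1542,Amide II,CR90
SRC and others,1455,C-O-H,CR65
SRC and others,1443,delta (CH2) [lipids fatty acids] or delta (CH) [polysaccharides pectin],CR65
SLM and others,1755,lipid,CR51
SLM and others,1735,C=O stretching the phenolic compound ellagic acid/the secondary metabolite quercetin,CR63
SLM and others,1512,nu (C-C) aromatic (conjugated with C=C phenolic compounds),CR62
SLM and others,1481,symmetric deformation NH2+ glyphosate,CR60
SLM and others,1466,CH2 bending in lipid,CR50
SOM and others,1755,lipid,CR51
SOM and others,1736,lipids,CR63
SOM and others,1481,symmetric deformation NH2+ glyphosate,CR60
SOM and others,1466,CH2 bending in lipid,CR50
SOM and others,1161,carbohydrate; stretching vibrations of hydrogen-bonding C-OH groups; cellulose,CR51
SOM and others,1103,nu(C-O-C) in ester,CR50
SAP and others,1755,lipid,CR51
SAP and others,1736,lipid,CR63
SAP and others,1481,symmetric deformation NH2+ glyphosate,CR60
SAP and others,1466,CH2 bending in lipid,CR50
SAP and others,1103,nu(C-O-C) in ester,CR50
ESA and others,1755,lipid,CR51
ESA and others,1732,lipid; fatty acid esters; hemicellulose,CR51
ESA and others,1647,amide I; pectin,CR51
ESA and others,1512,nu(C=C) in lignin carotenoid or protein,CR50
ESA and others,1481,symmetric deformation NH2+ glyphosate,CR60
ESA and others,1466,aromatic ring stretch vibrations tannins,CR61
ESB and others,1755,lipid,CR51
ESB and others,1736,C=O stretching [lipids],CR65
ESB and others,1481,symmetric deformation NH2+ glyphosate,CR60
ESB and others,1466,CH2 bending in lipid or aromatic ring stretch vibrations tannins,CR50
EDB and others,1728,nu (C=O) ester cutin,CR62
EDB and others,1446,aromatic ring stretch vibrations tannins,CR61
EDB and others,1408,CH3 deformation nu_s (COO-) in pectin,CR50
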