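hmdb_id	kegg_id	name	formula	monoisotopic_mass	endogenous_or_essential
KEGG:C00705	C00705	2'-Deoxycytidine diphosphate (dCDP)	C9H15N3O10P2	387.023267	true
KEGG:C00068	C00068	Thiamin diphosphate	C12H18N4O7P2S	424.037143	true
KEGG:C12270	C12270	N-Acetylaspartylglutamic acid	C11H16N2O8	304.090665	true
KEGG:C13828	C13828	Cervonoyl ethanolamide	C24H37NO2	371.282429	true
KEGG:C06197	C06197	Diadenosine triphosphate	C20H27N10O16P3	756.081935	true
KEGG:C00206	C00206	2'-Deoxyadenosine 5'-diphosphate	C10H15N5O9P2	411.034500	true
KEGG:C16511	C16511	l-Homocysteic acid	C4H9NO5S	183.020143	true
KEGG:C03287	C03287	l-Glutamic acid 5-phosphate	C5H10NO7P	227.019488	true
KEGG:C06232	C06232	Molybdate	H2MoO4	163.900717	true
KEGG:C01060	C01060	3,5-Diiodo-l-tyrosine	C9H9I2NO3	432.867189	true
KEGG:C00131	C00131	2'-Deoxyadenosine 5'-triphosphate (dATP)	C10H16N5O12P3	491.000831	true
KEGG:C00513	C00513	CDP-glycerol	C12H21N3O13P2	477.054961	true
KEGG:C01345	C01345	2'-Deoxyinosine triphosphate	C10H15N4O13P3	491.984846	true
KEGG:C05704	C05704	Selenocystine	C6H12N2O4Se2	335.912749	true
KEGG:C06125	C06125	3-O-Sulfogalactosylceramide (d18:1/14:0)	C38H73NO11S	751.490433	true
KEGG:C03451	C03451	S-Lactoylglutathione	C13H21N3O8S	379.104936	true
KEGG:C00440	C00440	5-Methyltetrahydrofolic acid	C20H25N7O6	459.186632	true
KEGG:C00032	C00032	Heme	C34H32FeN4O4	616.177293	true
KEGG:C04426	C04426	UDP-N-acetylgalactosamine 4-sulfate	C17H27N3O20P2S	687.038385	true
KEGG:C00024	C00024	Acetyl-CoA	C23H38N7O17P3S	809.125774	true
KEGG:C00798	C00798	Formyl-CoA	C22H36N7O17P3S	795.110124	true
KEGG:C11499	C11499	(S)-3-Sulfonatolactate	C3H6O6S	169.988509	true
KEGG:C02470	C02470	Xanthurenic acid	C10H7NO4	205.037508	true
KEGG:C00836	C00836	Sphinganine	C18H39NO2	301.298079	true
KEGG:C00104	C00104	Inosine 5'-diphosphate (IDP)	C10H14N4O11P2	428.013431	true
KEGG:C06054	C06054	2-Oxo-3-hydroxy-4-phosphobutanoic acid	C4H7O8P	213.987854	true
KEGG:C00081	C00081	Inosine triphosphate (ITP)	C10H15N4O14P3	507.979761	true
KEGG:C03204	C03204	10-Formyldihydrofolate	C20H21N7O7	471.150246	true
KEGG:C00006	C00006	NADP	C21H28N7O17P3	743.075452	true
KEGG:C02739	C02739	Phosphoribosyl-ATP	C15H25N5O20P4	719.004335	true
KEGG:C01190	C01190	Glucosylceramide (d18:1/25:0)	C49H95NO8	825.705769	true
KEGG:C05527	C05527	3-Sulfinylpyruvic acid	C3H4O5S	151.977944	true
KEGG:C05688	C05688	l-Selenocysteine	C3H7NO2Se	168.964200	true
KEGG:C05925	C05925	Dihydroneopterin phosphate	C9H14N5O7P	335.063084	true
KEGG:C00119	C00119	Phosphoribosyl pyrophosphate (PRPP)	C5H13O14P3	389.951815	true
KEGG:C00445	C00445	(6R)-5,10-Methenyltetrahydrofolate	C20H21N7O6	455.155331	true
KEGG:C19851	C19851	ADP-ribose 1''-2'' cyclic phosphate	C15H22N5O16P3	621.027440	true
KEGG:C04856	C04856	NADHX	C21H31N7O15P2	683.135337	true
KEGG:C00005	C00005	NADPH	C21H30N7O17P3	745.091102	true
KEGG:C05692	C05692	Se-Adenosyl-l-selenohomocysteine	C14H20N6O5Se	432.066039	true
KEGG:C00002	C00002	Adenosine triphosphate (ATP)	C10H16N5O13P3	506.995745	true
KEGG:C00130	C00130	Inosine monophosphate (IMP)	C10H13N4O8P	348.047100	true
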