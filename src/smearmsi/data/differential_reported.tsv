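mz	adduct	kegg_id	setting	cell_type
367.99194	M-H20-H	C00705	D0-	RBC
423.02167	M-H	C00068	D1-	RBC
607.17777	2M-H	C12270	D1-	RBC
743.53308	2M-H	C13828	D1-	RBC
755.09679	M-H	C06197	D1-	RBC
821.05335	2M-H	C00206	D1-	RBC
221.97144	M+K	C16511	D0+	RBC
265.96063	M+K	C03287	D0+	RBC
326.77131	2M+H	C06232	D0+	RBC
415.84174	M+H-H2O	C01060	D0+	RBC
456.0047	M+H-2H2O	C00131	D0+	RBC
500.04952	M+Na	C00513	D0+	RBC
514.96755	M+Na	C01345	D0+	RBC
694.83621	2M+Na	C05704	D0+	RBC
790.43199	M+K	C06125	D0+	RBC
418.04554	M+K	C03451	D1+	RBC
498.14504	M+K	C00440	D1+	RBC
616.17073	M+H	C00032	D1+	RBC
652.04788	M+H-2H2O	C04426	D1+	RBC
774.11178	M+H-2H2O	C00024	D1+	RBC
796.1011	M+H	C00798	D1+	RBC
338.96305	2M-H	C11499	D0-	WBC
367.99194	M-H20-H	C00705	D0-	WBC
409.06403	2M-H	C02470	D0-	WBC
601.60302	2M-H	C00836	D0-	WBC
409.00689	M-H20-H	C00104	D1-	WBC
426.95079	2M-H	C06054	D1-	WBC
488.97877	M-H20-H	C00081	D1-	WBC
506.11841	M+Cl	C03204	D1-	WBC
506.99341	M-H	C00081	D1-	WBC
724.08168	M-H20-H	C00006	D1-	WBC
743.53308	2M-H	C13828	D1-	WBC
753.97899	M+Cl	C02739	D1-	WBC
806.70364	M-H20-H	C01190	D1-	WBC
221.97144	M+K	C16511	D0+	WBC
265.96063	M+K	C03287	D0+	WBC
326.9293	2M+Na	C05527	D0+	WBC
376.89968	2M+K	C05688	D0+	WBC
415.84174	M+H-H2O	C01060	D0+	WBC
456.0047	M+H-2H2O	C00131	D0+	WBC
694.83621	2M+Na	C05704	D0+	WBC
701.98995	M+H-H2O	C02739	D0+	WBC
709.07265	2M+K	C05925	D0+	WBC
762.92406	2M+H-H2O	C00119	D0+	WBC
478.16774	M+Na	C00445	D1+	WBC
586.02355	M+H-2H2O	C19851	D1+	WBC
706.13261	M+Na	C04856	D1+	WBC
728.10302	M+H-H2O	C00005	D1+	WBC
779.09063	M+Na	C06197	D1+	WBC
865.13597	2M+H	C05692	D1+	WBC
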