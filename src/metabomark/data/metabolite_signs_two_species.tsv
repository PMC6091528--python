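metabolite	h_versicolor	a_americanus
Adenosine	+	-
Butyric acid	+
Creatinine	+	+
Galactose	+	+
Glucose	+	+
Glutamic acid	-	-
Maltose	+	+
Mannose		-
Ribose	-	-
Gluconic acid		-
Glutaric acid	-	+
Glycine	+	+
Guanosine	+	-
Inosine	+	+
Alanine	+
Asparagine	+
Aspartic acid	-
Leucine	-
Lysine	-
Phenylalanine	-
Proline	+	+
Serine	+	+
Threonine	-	-
Tryptophan	+
Tyrosine	-
Linoleic acid		-
Maleic acid	+
Myoinositol	-	+
Niacinamide	-
Ornithine	+
Palmitic acid	+	-
Phosphate	+	+
Phosphoric acid	+
Lactic acid	+	+
Pterin	+
Purine	+	+
Putrescine	+
Pyrimidine	-	+
Stearic acid	+	-
Succinic acid	-	+
Urea	+
Uric acid	-
Uridine	+
Valeric acid	+
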