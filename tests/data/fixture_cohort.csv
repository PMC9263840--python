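case_id,subtype,center,has_resegmentation,age,tumor_size,bpe,fgt,margin,aln_short_diameter,firmness,mobility,menopause
center1_0000,HR-positive,center1,False,54.77906892848532,13.10523922152785,moderate,non-dense,clear,<=5mm,hard,non-pushable,post
center1_0001,HR-positive,center1,False,51.87882220938217,12.019208798206,mild,non-dense,blurry,<=5mm,hard,non-pushable,pre
center1_0002,HR-positive,center1,False,32.17101664063432,12.762390801678915,moderate,dense,clear,<=5mm,hard,pushable,pre
center1_0003,HR-positive,center1,False,46.455814245463415,12.473568716373421,marked,non-dense,clear,<=5mm,soft,pushable,post
center1_0004,HR-positive,center1,False,51.438426886613236,13.267624813764378,marked,non-dense,blurry,<=5mm,soft,non-pushable,pre
center1_0005,HR-positive,center1,False,46.901978305005855,13.857583998522749,moderate,dense,clear,<=5mm,hard,pushable,post
center1_0006,HER2-enriched,center1,True,44.42332317783071,11.094577818886531,marked,non-dense,clear,>5mm,hard,non-pushable,post
center1_0007,HER2-enriched,center1,True,53.43186153047392,13.690322047809294,mild,non-dense,clear,>5mm,hard,non-pushable,post
center1_0008,HER2-enriched,center1,True,49.27854331001933,11.555844513869967,moderate,non-dense,blurry,<=5mm,hard,non-pushable,pre
center1_0009,TNBC,center1,False,44.71792626414091,13.724239067133869,moderate,dense,blurry,<=5mm,hard,non-pushable,pre
center1_0010,TNBC,center1,True,38.39179486458045,11.683000159852273,mild,non-dense,clear,<=5mm,hard,non-pushable,pre
center1_0011,TNBC,center1,False,50.496695665456095,13.05872010025035,moderate,non-dense,blurry,>5mm,hard,non-pushable,pre
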