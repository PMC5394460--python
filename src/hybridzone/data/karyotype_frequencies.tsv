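arm	label	safim_coluzzii	safim_admixed	safim_gambiae	leibala_gambiae
2R	+/+	0	25.0	23.7	6.9
2R	+/d	66.7	56.6	51.8	8.6
2R	d/d	16.7	17.1	22.8	0
2R	+/b	0	0	0	29.3
2R	b/b	0	0	0	17.2
2R	bd/+, b/d	16.7	0	0.9	8.6
2R	jb/+, j/b	0	0	0	10.3
2R	jbd/+, j/bd, jb/d	0	0	0	6.9
2R	jb/b	0	0	0	3.4
2R	jbd/b, jb/bd	0	0	0	5.2
2R	jb/d, jd/b, j/bd	0	0	0	3.4
2R	bd/d	0	0	0.9	0
2R	d/u	0	1.3	0	0
2L	+/+	66.7	61.8	61.4	5.2
2L	+/a	33.3	32.9	36.8	32.8
2L	a/a	0	5.3	1.8	62.1
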