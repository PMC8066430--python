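item_id	rater_id	framework	code
i1	A	composite	R_B[b28013]*S[d760]
i1	B	composite	R_B[b28013]*S[d760]
i2	A	composite	R_X[nd-gh]
i2	B	composite	R_X[nd-gh]
i3	A	composite	E_B[b4200]/S[d7100]
i3	B	composite	E_S[d7100]/B[b4200]
i4	A	composite	R_P[b152]
i4	B	composite	E_P[b152]
i5	A	composite	R_B[b28013]*S[d760]
i5	B	composite	R_B[b28013]*S[d760]
i6	A	composite	R_S[d760],P[b152]
i6	B	composite	R_P[b152],S[d760]
i1	A	ipc	R_B*S
i1	B	ipc	R_B*S
i2	A	ipc	R_X
i2	B	ipc	R_X
i3	A	ipc	E_B/S
i3	B	ipc	E_S/B
i4	A	ipc	R_P
i4	B	ipc	E_P
i5	A	ipc	R_B*S
i5	B	ipc	R_B*S
i6	A	ipc	R_S,P
i6	B	ipc	R_P,S
i1	A	icf	b28013;d760
i1	B	icf	d760;b28013
i2	A	icf	nd-gh
i2	B	icf	nd-gh
i3	A	icf	b4200;d7100
i3	B	icf	d7100;b4200
i4	A	icf	b152
i4	B	icf	b152
i5	A	icf	b28013;d760
i5	B	icf	b28013;d760
i6	A	icf	b152;d760
i6	B	icf	d760;b152
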