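signature	hypothesis	description
0000	none	no introgression detected
++00	anc12_P3	introgression between ancestor(P1,P2) and P3
--00	anc12_P4	introgression between ancestor(P1,P2) and P4
+0++	P3_into_P1	introgression from P3 into P1 (directional)
+++0	P1_into_P3	introgression from P1 into P3 (directional)
-0++	P4_into_P1	introgression from P4 into P1 (directional)
--0+	P1_into_P4	introgression from P1 into P4 (directional)
0+--	P3_into_P2	introgression from P3 into P2 (directional)
++-0	P2_into_P3	introgression from P2 into P3 (directional)
0---	P4_into_P2	introgression from P4 into P2 (directional)
--0-	P2_into_P4	introgression from P2 into P4 (directional)
+0+0	P1_P3_uncertain	introgression between P1 and P3, direction uncertain or reciprocal
-00+	P1_P4_uncertain	introgression between P1 and P4, direction uncertain or reciprocal
0+-0	P2_P3_uncertain	introgression between P2 and P3, direction uncertain or reciprocal
0-0-	P2_P4_uncertain	introgression between P2 and P4, direction uncertain or reciprocal
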