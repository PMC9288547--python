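sample	group	t1	t2	c	reported
A_pierrei	authentic_target	++	++	++	Aristolochia sp.
A_pothieri	authentic_target	++	++	++	Aristolochia sp.
A_acuminata	authentic_target	++	++	++	Aristolochia sp.
A_gigantea	authentic_target	++	++	++	Aristolochia sp.
A_grandiflora	authentic_target	++	++	++	Aristolochia sp.
A_cambodiana	authentic_target	++	++	++	Aristolochia sp.
A_littoralis	authentic_target	++	++	++	Aristolochia sp.
A_ringens	authentic_target	++	++	++	Aristolochia sp.
A_tentaculata	authentic_target	++	++	++	Aristolochia sp.
C_pulchellum	authentic_nontarget	++	-	++	Non-Aristolochia sp.
T_scabra	authentic_nontarget	++	-	++	Non-Aristolochia sp.
J_sambac	authentic_nontarget	++	-	++	Non-Aristolochia sp.
J_adenophyllum	authentic_nontarget	++	-	++	Non-Aristolochia sp.
C1	crude_drug	+	++	++	Aristolochia sp.
C2	crude_drug	+	++	++	Aristolochia sp.
C3	crude_drug	+	++	++	Aristolochia sp.
C4	crude_drug	+	++	++	Aristolochia sp.
C5	crude_drug	+	-	++	Non-Aristolochia sp.
C6	crude_drug	+	++	++	Aristolochia sp.
C7	crude_drug	+	++	++	Aristolochia sp.
C8	crude_drug	+	++	++	Aristolochia sp.
F0_YMVT	formula	++	-	++	Non-Aristolochia sp.
F1	formula	++	++	++	Aristolochia sp.
F2	formula	+	+	++	Aristolochia sp.
F3	formula	++	-	++	Non-Aristolochia sp.
F4	formula	++	+	++	Aristolochia sp.
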