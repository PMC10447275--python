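# Rabbit eye / dexamethasone release-mode parameter set (flat dialect).
# Values carry the units in which they are reported in the literature.
mode = release

# anatomy
V_t = 7E-03 mL
V_Vit = 1.7 mL
V_ScCh = 0.361 mL
V_Ret = 0.086 mL
V_Aq = 0.325 mL
A_Globe = 8.6 cm2
A_Palp = 14 cm2
A_Bulb = 3 cm2
# suggested working values (no reported rabbit value)
A_Cornea = 2.0 cm2
A_SCL = 2.27 cm2

# physiology
Q_UvSc = 0.176 uL/min
Q_Vit_Aq = 0.19 uL/min
Q_Aq = 4.2 uL/min
Q_Drain = 0.5 uL/min
Clearance_ScCh = 1 mL/min

# drug
K_t = 1
K_Aq = 1
K_Vit = 1
K_ScCh = 15
K_Ret = 10
P_Conj = 2.50E-06 cm/s
P_ScCh_Ret = 10E-06 cm/s
P_Ret_Vit = 1.3E-05 cm/s
F = 2.08 %

# release curve (representative sandwich-lens values, not literature data)
M_Released = 2.0E05 ng
T = 2 day
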