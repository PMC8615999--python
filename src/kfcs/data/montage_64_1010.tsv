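Fp1	-0.0904	0.9200
Fpz	0.0000	0.9200
Fp2	0.0904	0.9200
AF7	-0.6237	0.7200
AF3	-0.2911	0.7200
AFz	0.0000	0.7200
AF4	0.2911	0.7200
AF8	0.6237	0.7200
F7	-0.7348	0.5000
F5	-0.5389	0.5000
F3	-0.3429	0.5000
F1	-0.1470	0.5000
Fz	0.0000	0.5000
F2	0.1470	0.5000
F4	0.3429	0.5000
F6	0.5389	0.5000
F8	0.7348	0.5000
FT7	-0.8034	0.2500
FC5	-0.5892	0.2500
FC3	-0.3749	0.2500
FC1	-0.1607	0.2500
FCz	0.0000	0.2500
FC2	0.1607	0.2500
FC4	0.3749	0.2500
FC6	0.5892	0.2500
FT8	0.8034	0.2500
T7	-0.8250	0.0000
C5	-0.6050	0.0000
C3	-0.3850	0.0000
C1	-0.1650	0.0000
Cz	0.0000	0.0000
C2	0.1650	0.0000
C4	0.3850	0.0000
C6	0.6050	0.0000
T8	0.8250	0.0000
TP7	-0.8034	-0.2500
CP5	-0.5892	-0.2500
CP3	-0.3749	-0.2500
CP1	-0.1607	-0.2500
CPz	0.0000	-0.2500
CP2	0.1607	-0.2500
CP4	0.3749	-0.2500
CP6	0.5892	-0.2500
TP8	0.8034	-0.2500
P9	-0.9308	-0.5000
P7	-0.7348	-0.5000
P5	-0.5389	-0.5000
P3	-0.3429	-0.5000
P1	-0.1470	-0.5000
Pz	0.0000	-0.5000
P2	0.1470	-0.5000
P4	0.3429	-0.5000
P6	0.5389	-0.5000
P8	0.7348	-0.5000
P10	0.9308	-0.5000
PO7	-0.6237	-0.7200
PO3	-0.2911	-0.7200
POz	0.0000	-0.7200
PO4	0.2911	-0.7200
PO8	0.6237	-0.7200
O1	-0.0904	-0.9200
Oz	0.0000	-0.9200
O2	0.0904	-0.9200
Iz	0.0000	-1.0500
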