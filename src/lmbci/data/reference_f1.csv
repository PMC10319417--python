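# Reference per-subject F1 scores (%) for the three pairwise decoding tasks,
# transcribed from the original study's published results table.
# Class1: imagery-vs-rest without kinesthetic illusion (no-LMI vs rest)
# Class2: imagery-vs-rest with kinesthetic illusion (KI-LMI vs rest)
# Class3: simulated-online pairing (KI-LMI vs V-rest)
subject,Class1,Class2,Class3
H1,63.9,76,81
H2,66.8,70.1,65.5
H3,78.7,74.9,58.3
H4,65,76.1,71.1
H5,75.0,77.3,69.1
H6,80.5,87.9,88.2
H7,83.0,84.2,72.3
H8,87.7,93.8,92.3
H9,70.8,82.1,83.9
H10,86.7,92,86.1
H11,65.1,80,69.3
H12,80.2,94.8,81.4
H13,66.9,77.3,72.9
H14,74.1,81.7,79.1
H15,64.9,78.5,68.9
H16,79.5,83.7,83.5
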