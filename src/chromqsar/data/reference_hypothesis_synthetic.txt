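# Synthetic stand-in reference pharmacophore hypothesis.
# Feature census mirrors a receptor-ligand hypothesis for a dihydropteroate
# synthase inhibitor (one H-bond acceptor, three H-bond donors, three
# aromatic rings); coordinates are constructed, not derived from any
# crystal structure.
# columns: kind x y z tolerance (Angstrom)
A   1.250   0.480  -0.730  1.0
D  -2.140   1.920   0.310  1.0
D  -3.050  -0.660   0.940  1.0
D   4.380   2.110  -0.220  1.0
R   0.000   0.000   0.000  1.0
R   3.420  -1.350   0.510  1.0
R  -1.760  -2.480  -0.640  1.0
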