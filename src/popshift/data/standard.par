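# Per-atom-type energy parameters (AutoDock4-family semi-empirical scoring).
# Columns:
#   type     atom-type code used in pdbq_charged files
#   r_eq     self-pair equilibrium distance Rii (Angstrom); pair r_eq is the
#            arithmetic mean of the two self-pair values
#   eps      well depth (kcal/mol); pair depth is the geometric mean
#   vol      atomic solvation volume (Angstrom^3)
#   solpar   atomic solvation parameter
#   hb       hydrogen-bond class: none | donor | acceptor | both
#   hb_r_eq  12-10 equilibrium distance (Angstrom), acceptor-side
#   hb_eps   12-10 well depth (kcal/mol), acceptor-side
#
# type  r_eq   eps     vol       solpar    hb        hb_r_eq  hb_eps
C       4.00   0.150   33.5103   -0.00143  none      0.0      0.0
A       4.00   0.150   33.5103   -0.00052  none      0.0      0.0
N       3.50   0.160   22.4493   -0.00162  none      0.0      0.0
NA      3.50   0.160   22.4493   -0.00162  acceptor  1.90     5.0
O       3.20   0.200   17.1573   -0.00251  acceptor  1.90     5.0
OA      3.20   0.200   17.1573   -0.00251  acceptor  1.90     5.0
S       4.00   0.200   33.5103   -0.00214  none      0.0      0.0
SA      4.00   0.200   33.5103   -0.00214  acceptor  2.50     1.0
H       2.00   0.020    0.0000    0.00051  none      0.0      0.0
HD      2.00   0.020    0.0000    0.00051  donor     0.0      0.0
P       4.20   0.200   38.7924   -0.00110  none      0.0      0.0
Mg      1.30   0.875    1.5600   -0.00110  none      0.0      0.0
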