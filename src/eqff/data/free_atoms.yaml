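# Free-atom reference parameters for the physics module.
#
# Units: polarizability alpha_free in bohr^3, dispersion coefficient C6_free
# in hartree*bohr^6, van der Waals radius r_vdw_free in bohr, free atomic
# volume v_free (<r^3> expectation value) in bohr^3. The loader converts to
# the package units (kcal/mol, Angstrom, e).
#
# alpha_free and C6_free are the standard free-atom values of Chu & Dalgarno
# (J. Chem. Phys. 121, 4083 (2004)) used by the Tkatchenko-Scheffler scheme;
# r_vdw_free are the free-atom vdW radii used in the original TS paper;
# v_free are free-atom <r^3> values from Kannemann & Becke-type tabulations.
# n_valence is the number of valence electrons.
H:  {n_valence: 1, alpha_free: 4.50,  c6_free: 6.50,   r_vdw_free: 3.10, v_free: 8.7}
C:  {n_valence: 4, alpha_free: 12.0,  c6_free: 46.6,   r_vdw_free: 3.59, v_free: 35.8}
N:  {n_valence: 5, alpha_free: 7.40,  c6_free: 24.2,   r_vdw_free: 3.34, v_free: 26.8}
O:  {n_valence: 6, alpha_free: 5.40,  c6_free: 15.6,   r_vdw_free: 3.19, v_free: 22.5}
F:  {n_valence: 7, alpha_free: 3.80,  c6_free: 9.52,   r_vdw_free: 3.04, v_free: 19.0}
S:  {n_valence: 6, alpha_free: 19.6,  c6_free: 134.0,  r_vdw_free: 3.86, v_free: 75.0}
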