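# Default atomic property scheme (version 1).
#
# Per-field atomic properties entering the similarity-index and probe-energy
# calculations.  All tables are keyed by element symbol; an element missing
# from a required table is an error, never silently defaulted.
name: default
version: 1

hydrogens: explicit          # charges and fields require explicit hydrogens
protonate_aliphatic_amines: true   # pH 7.4 convention; aliphatic amines -> +1

# van der Waals radii (Angstrom, Bondi compilation).  The CoMSIA steric
# property is (r_vdw / r_vdw[C])**3 so that carbon is exactly 1.0.
vdw_radius:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  Cl: 1.75
  Br: 1.85
  I: 1.98

# Atomic hydrophobicity: per-atom logP contributions.
# method "crippen" uses the published Wildman-Crippen atomic contribution
# table shipped with RDKit.
hydrophobicity:
  method: crippen

# Lennard-Jones well depths (kcal/mol) and minimum-energy radii (Angstrom),
# a generic vdW parameter set for the 6-12 probe energies.
lennard_jones:
  probe:            # sp3-carbon probe
    radius: 1.70
    epsilon: 0.107
  atoms:
    H:  {radius: 1.50, epsilon: 0.042}
    C:  {radius: 1.70, epsilon: 0.107}
    N:  {radius: 1.55, epsilon: 0.095}
    O:  {radius: 1.52, epsilon: 0.116}
    F:  {radius: 1.47, epsilon: 0.109}
    P:  {radius: 1.80, epsilon: 0.200}
    S:  {radius: 1.80, epsilon: 0.314}
    Cl: {radius: 1.75, epsilon: 0.314}
    Br: {radius: 1.85, epsilon: 0.434}
    I:  {radius: 1.98, epsilon: 0.600}

# Hydrogen-bond donor/acceptor flags by substructure rule.  Flags are set on
# the heavy atom (the N of an N-H donor, not the hydrogen).
donor_smarts:
  - "[N;!H0;!$([N+]([O-]))]"
  - "[O;!H0]"
acceptor_smarts:
  - "[O;!$([O-][N+])]"          # every neutral-framework oxygen, incl. S=O
  - "[N;H0;!$([N+]);!$(N=[N+]=[N-]);!$([N;H0]a)]"
  - "[n;H0;!$([n+])]"
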