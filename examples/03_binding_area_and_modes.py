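"""Contact-frequency binding area and binding-mode classification.

The binding area is defined purely by how often residues sit within
4 A of an inhibitor; binding modes are fixed geometric motifs (the
amine network, the polar anchor, the covalent serine contact).
"""

from dpp4var import (
    EnsembleSpec,
    binding_area_from_contacts,
    classify_binding_modes,
    generate_units,
)

units, _, truth = generate_units(EnsembleSpec(seed=3))

area = binding_area_from_contacts(units)
print(f"{area.n_ligands} distinct ligand(s) across {area.n_units} units")
print(f"core set (>70 % contact): {sorted(area.core_set)}")
print(f"extended set (>30 %):     {sorted(area.extended_set)}")

n_amine = n_anchor = n_covalent = 0
for u in units:
    rec = classify_binding_modes(u, truth.role_map)
    n_amine += rec.amine_network
    n_anchor += rec.polar_anchor
    n_covalent += rec.covalent_ser630
n = len(units)
print(f"amine network  {n_amine}/{n} units  (one primary/secondary amine N "
      f"<4/<4/<5 A to the two glutamate OE and the tyrosine OH)")
print(f"polar anchor   {n_anchor}/{n} units  (O/N/halogen <4 A to Arg NH or Asn ND/OD)")
print(f"covalent SER   {n_covalent}/{n} units (ligand C <3 A to the serine OG; "
      f"noise occasionally pushes the planted 2.8 A contact past 3 A)")
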