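"""Detect conserved water sites and compare against the planted truth.

Waters from all units are mapped into one reference frame by the
global Calpha superposition and clustered with the 1 A identity rule;
a site's support is the number of units contributing a member.
"""

import numpy as np

from dpp4var import (
    EnsembleSpec,
    annotate_water_sites,
    consensus_water_sites,
    generate_units,
)

units, _, truth = generate_units(EnsembleSpec(seed=19))
sites = consensus_water_sites(units, min_support=1)
annotate_water_sites(sites, None, units)

print(f"{sum(len(u.waters) for u in units)} waters over {len(units)} units "
      f"-> {len(sites)} sites")
print("top sites (support, mean B):",
      [(s.support, round(s.mean_b, 1)) for s in sites[:6]])

ref = units[0].unit_id
for k, planted in enumerate(truth.planted_sites):
    expected = truth.site_position_in_unit_frame(k, ref)
    match = min(sites, key=lambda s: np.linalg.norm(s.centroid - expected))
    d = np.linalg.norm(match.centroid - expected)
    print(f"planted site {k}: true support {len(planted['unit_ids'])}, "
          f"detected support {match.support}, centroid error {d:.2f} A, "
          f"low-B flags {match.b_below_water_avg}/{match.b_below_protein_avg}")
# Planted sites carry B ~10 A^2 vs ~40 A^2 for decoys, so they flag as
# lower than both the water and the protein B-factor averages.
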