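# dpp4var

Ensemble comparison of protein–inhibitor cocrystal structures.

When dozens of crystal structures of the same drug target exist, each
solved with a different inhibitor, a basic pharmacological question
becomes quantitative: does the protein change shape according to the
inhibitor, or does it present an essentially rigid site with a common
binding rule? The motivating case is dipeptidyl peptidase IV (DPP-4),
a type-2-diabetes target with a large redundant set of inhibitor
cocrystals (the gliptin drug class). `dpp4var` implements the
complete comparison as a reusable, tested library:

* **unit extraction** — one protein copy (residues 41–764 by
  default), the inhibitor at its active centre, and first-shell
  waters (< 4 Å), with disorder and ligand-selection rules;
* **superposition** — Kabsch least-squares rigid fit;
  `RMSD = √((1/N) Σᵢ χᵢ²)` over all unit pairs;
* **variation profiles** — per-residue mean post-superposition
  displacement `(1/M) Σₖ δᵢₖ`, globally fitted for Cα atoms and
  locally (N/Cα/C frame) for side-chain reporter atoms (Arg Nη,
  Tyr Oη, Ser Oγ, …);
* **binding area** — residues within 4 Å of more than 70 % (core) or
  30 % (extended) of distinct inhibitors;
* **binding modes** — the amine network (one primary/secondary amine
  N simultaneously < 4 Å to Glu205 Oε and Glu206 Oε and < 5 Å to
  Tyr662 Oη), the Arg125/Asn710 polar anchor (< 4 Å), and the
  covalent Ser630 nitrile contact (< 3 Å);
* **conserved waters** — consensus sites from the 1 Å identity rule
  with per-unit support, proximity flags and B-factor comparison
  against water and protein averages;
* **exposed surface area** — per-residue Shrake–Rupley areas with
  waters and ligand removed, averaged over units;
* **synthetic ensembles** — a generator that plants known
  displacement scales, binding geometry and conserved water sites,
  written out as legal PDB files, so every stage is verifiable
  against ground truth without downloading structures.

## Worked example

`examples/02_superposition_and_variation.py` generates ten synthetic
units with 0.2 Å per-atom Gaussian displacement and random rigid
poses, then measures what the analysis recovers:

```
pairs: 45  mean RMSD 0.485 A  max 0.505 A
theory: sigma*sqrt(6) = 0.490 A
mean Calpha variation 0.448 A (theory 4*sigma/sqrt(pi) = 0.451 A)
recovered sigma: 0.198 A (planted 0.2)
```

The 45 pairwise RMSDs concentrate around σ√6 because a difference of
two σ-noised copies has per-coordinate variance 2σ²; the per-residue
variation matches the Maxwell mean 4σ/√π, and inverting it recovers
the planted scale to 1 %. The other examples cover simulation
(`01`), binding area and modes (`03`), conserved waters (`04`),
surface area (`05`) and the end-to-end pipeline (`06`), each printing
the numbers it computes and what they mean.

For shell use there is a thin CLI:

```sh
dpp4var simulate --out-dir pdbs/ --truth truth.json --seed 7
dpp4var run --config run.yaml      # writes units.json, *.tsv, report.json
```

On real data, point `input_dir` at downloaded PDB entries and keep
the defaults (span 41–764, active-site residue 630, the DPP-4 site
map in `dpp4var.DEFAULT_SITE_MAP`).

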