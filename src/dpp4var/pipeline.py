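"""End-to-end orchestration: extract units, superpose, measure, report.

The pipeline reads a directory of PDB files, applies the unit-selection
rules to each, and runs every analysis stage on the accepted units:

========================  =====================================
stage                     output file
========================  =====================================
unit extraction           ``units.json``
all-pairs Calpha RMSD     ``rmsd_summary.tsv``
Calpha variation          ``calpha_variation.tsv``
side-chain variation      ``sidechain_variation.tsv``
binding area              ``area.tsv``
binding modes             ``modes.tsv``
conserved waters          ``waters.tsv``
exposed surface area      ``sasa.tsv``
headline aggregates       ``report.json``
========================  =====================================

``report.json`` echoes every threshold for provenance and is
deterministic given the same inputs and configuration, except for its
``generated_at`` timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts, sasa, structure_io, variation, waters

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    input_dir: str
    out_dir: str
    span: tuple[int, int] = (41, 764)
    active_site_residue: int = 630
    ligand_cutoff: float = 4.0
    water_cutoff: float = 4.0
    max_disordered: int = 6
    contact_cutoff: float = 4.0
    high_fraction: float = 0.70
    low_fraction: float = 0.30
    identity_radius: float = 1.0
    min_support_fraction: float = 0.427
    site_map: dict[str, int] | None = None
    reference_unit: str | None = None
    require_ligand: bool = True
    all_chains: bool = True
    chain_overrides: dict[str, str] = field(default_factory=dict)
    sasa_probe: float = 1.4
    sasa_points: int = 960
    seed: int = 0

    def __post_init__(self) -> None:
        self.span = tuple(self.span)  # type: ignore[assignment]
        for name in ("ligand_cutoff", "water_cutoff", "contact_cutoff",
                     "identity_radius", "sasa_probe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["span"] = list(self.span)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "span" in d:
            d["span"] = tuple(d["span"])
        return cls(**d)


def _extract_units(config: RunConfig):
    in_dir = Path(config.input_dir)
    files = sorted(in_dir.glob("*.pdb"))
    if not files:
        raise PipelineError(f"no .pdb files in {in_dir}")
    units, rejections, manifest = [], [], []
    for path in files:
        entry = path.stem
        model = structure_io.parse_pdb(path.read_text())
        chain_ids = model.chain_ids()
        if entry in config.chain_overrides:
            chain_ids = [config.chain_overrides[entry]]
        accepted_for_entry = 0
        for chain_id in chain_ids:
            uid = f"{entry}_{chain_id}" if not entry.endswith(f"_{chain_id}") else entry
            result = structure_io.build_unit(
                model, chain_id, unit_id=uid,
                span=config.span,
                active_site_residue=config.active_site_residue,
                ligand_cutoff=config.ligand_cutoff,
                water_cutoff=config.water_cutoff,
                max_disordered=config.max_disordered,
                require_ligand=config.require_ligand,
            )
            if isinstance(result, structure_io.UnitRejection):
                log.info("rejected %s: %s", result.unit_id, result.reason)
                rejections.append(result)
                continue
            units.append(result)
            accepted_for_entry += 1
            manifest.append({
                "unit_id": result.unit_id,
                "source": path.name,
                "chain": chain_id,
                "disordered_count": result.disordered_count,
                "ligand": result.ligand.identifier if result.ligand else None,
                "n_waters": len(result.waters),
            })
            if not config.all_chains:
                break
        if accepted_for_entry == 0:
            log.warning("entry %s produced no accepted unit", entry)
    return units, rejections, manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dictionary."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    units, rejections, manifest = _extract_units(config)
    (out / "units.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if len(units) < 2:
        raise PipelineError(f"only {len(units)} accepted unit(s); need at least 2")
    log.info("accepted %d units (%d rejected)", len(units), len(rejections))

    report: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_units": len(units),
        "n_rejected": len(rejections),
        "rejections": [{"unit_id": r.unit_id, "reason": r.reason} for r in rejections],
    }

    summary = variation.rmsd_summary(units)
    summary.pairs.to_csv(out / "rmsd_summary.tsv", sep="\t", index=False)
    report["mean_pairwise_rmsd_A"] = round(summary.mean, 4)
    report["max_pairwise_rmsd_A"] = round(summary.maximum, 4)
    report["n_pairs"] = int(len(summary.pairs))
    log.info("RMSD stage done: mean %.3f A, max %.3f A", summary.mean, summary.maximum)

    profiles = variation.calpha_variation(units)
    pd.DataFrame(
        [(p.residue_number, p.amino_acid, "CA", round(p.variation, 4), p.n_combinations)
         for p in profiles.values()],
        columns=["residue_number", "amino_acid", "atom_role", "variation_A", "n_pairs"],
    ).to_csv(out / "calpha_variation.tsv", sep="\t", index=False)
    mean_var = sum(p.variation for p in profiles.values()) / len(profiles)
    report["mean_calpha_variation_A"] = round(mean_var, 4)

    sc = variation.sidechain_variation_all(units)
    sc.round(4).to_csv(out / "sidechain_variation.tsv", sep="\t", index=False)
    if len(sc):
        report["mean_sidechain_variation_A"] = round(float(sc["variation_A"].mean()), 4)

    area = None
    has_ligands = any(u.ligand is not None for u in units)
    if has_ligands:
        area = contacts.binding_area_from_contacts(
            units, cutoff=config.contact_cutoff,
            high_fraction=config.high_fraction, low_fraction=config.low_fraction)
        pd.DataFrame(
            sorted(
                (num, frac, area.per_unit_counts[num],
                 num in area.core_set, num in area.extended_set)
                for num, frac in area.per_residue_contact_fraction.items()
            ),
            columns=["residue_number", "ligand_contact_fraction", "n_units_in_contact",
                     "core", "extended"],
        ).round(4).to_csv(out / "area.tsv", sep="\t", index=False)
        report["binding_area_core"] = sorted(area.core_set)
        report["binding_area_extended"] = sorted(area.extended_set)
        report["n_distinct_ligands"] = area.n_ligands

        if config.site_map is not None:
            records = [
                contacts.classify_binding_modes(u, config.site_map)
                for u in units if u.ligand is not None
            ]
            pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
                out / "modes.tsv", sep="\t", index=False)
            n_lig_units = len(records)
            report["amine_network_units"] = sum(r.amine_network for r in records)
            report["amine_network_fraction"] = round(
                report["amine_network_units"] / n_lig_units, 4)
            report["polar_anchor_units"] = sum(r.polar_anchor for r in records)
            report["covalent_ser630_units"] = sum(r.covalent_ser630 for r in records)
        else:
            log.info("no site_map configured; binding-mode stage skipped")
    else:
        log.info("no ligands present; contact stages skipped")

    wet = [u for u in units if u.waters]
    if wet:
        sites = waters.consensus_water_sites(
            units, reference_unit=config.reference_unit,
            identity_radius=config.identity_radius,
            min_support_fraction=config.min_support_fraction)
        waters.annotate_water_sites(sites, area, units)
        pd.DataFrame(
            [(s.site_id, *np.round(s.centroid, 3), s.support, round(s.mean_b, 2),
              s.near_binding_area, s.near_ligand_count,
              s.b_below_water_avg, s.b_below_protein_avg)
             for s in sites],
            columns=["site_id", "x", "y", "z", "support", "mean_b",
                     "near_binding_area", "near_ligand_count",
                     "b_below_water_avg", "b_below_protein_avg"],
        ).to_csv(out / "waters.tsv", sep="\t", index=False)
        report["n_conserved_water_sites"] = len(sites)
        report["top_water_supports"] = [s.support for s in sites[:10]]
    else:
        log.info("no waters present; water stage skipped")

    mean_area = sasa.ensemble_mean_sasa(
        units, probe_radius=config.sasa_probe, n_points=config.sasa_points)
    pd.DataFrame(
        [(num, round(a, 2)) for num, a in mean_area.items()],
        columns=["residue_number", "exposed_area_A2"],
    ).to_csv(out / "sasa.tsv", sep="\t", index=False)
    report["mean_exposed_area_A2"] = round(
        sum(mean_area.values()) / len(mean_area), 2)

    report["generated_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return report
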