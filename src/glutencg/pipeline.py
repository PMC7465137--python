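"""Full-study orchestration: profile → build → simulate → analyze.

A :class:`PipelineConfig` (YAML-serializable) drives, per sequence ×
salt × restraint mode: hydropathy/charge reports, a persisted ensemble,
and analysis summaries.  Runs are idempotent for a fixed master seed; a
manifest lists every artifact with checksums, and the verbatim config
is written into the output directory.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import analysis, mc, model, profiles, scales, sequence_io, synthetic


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a study run."""

    fasta: Optional[str] = None
    synthetic_params: Optional[dict] = None  # GlutenSequenceParams kwargs
    signal_peptide_lengths: Dict[str, int] = field(default_factory=dict)
    his_positive: bool = False
    charged_termini: bool = False
    hydropathy_window: int = 15
    energy: dict = field(default_factory=dict)  # EnergyModelParams kwargs
    salts_mM: List[float] = field(default_factory=lambda: [10.0, 80.0, 500.0, 1000.0])
    restraint_pairs: Dict[str, List[List[int]]] = field(default_factory=dict)
    restraint_modes: List[str] = field(default_factory=lambda: ["without", "with"])
    n_equilibration_sweeps: int = 300
    n_production_sweeps: int = 1000
    thinning: int = 10
    outdir: str = "glutencg_out"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_sequences(config: PipelineConfig) -> List[sequence_io.ProteinSequence]:
    seqs: List[sequence_io.ProteinSequence] = []
    if config.fasta:
        seqs.extend(sequence_io.read_fasta(config.fasta))
    if config.synthetic_params is not None:
        params = synthetic.GlutenSequenceParams(**config.synthetic_params)
        seqs.append(synthetic.generate_gluten_like_sequence(params))
    if not seqs:
        raise ValueError("config provides neither a FASTA path nor synthetic params")
    return [
        sequence_io.trim_signal_peptide(s, config.signal_peptide_lengths.get(s.id, 0))
        for s in seqs
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured study; returns the result bundle.

    Output layout: ``<outdir>/<seq_id>/`` holds the profile CSV and
    charge-census JSON; each simulation writes
    ``salt<mM>_<mode>.npz`` and a matching ``_summary.json``.  Partial
    outputs from a failed stage are quarantined under ``quarantine/``
    with an error manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    scheme = scales.charge_scheme(config.his_positive, config.charged_termini)
    kd = scales.kyte_doolittle()
    eparams = model.EnergyModelParams(**config.energy)
    bundle: dict = {"outdir": str(outdir), "sequences": {}}
    artifacts: List[Path] = [outdir / "config.yaml"]

    try:
        for seq in _load_sequences(config):
            seq_dir = outdir / seq.id
            seq_dir.mkdir(exist_ok=True)
            prof = profiles.hydropathy_profile(seq, kd, config.hydropathy_window)
            prof_csv = seq_dir / "hydropathy.csv"
            prof.to_csv(prof_csv, seq)
            census = profiles.charge_census(seq, scheme)
            census_json = seq_dir / "charge_census.json"
            census.to_json(census_json)
            artifacts += [prof_csv, census_json]

            pairs = [tuple(p) for p in config.restraint_pairs.get(seq.id, [])]
            runs: dict = {}
            for mode in config.restraint_modes:
                use_pairs = pairs if mode == "with" else []
                if mode == "with" and not pairs:
                    continue
                cfg = mc.MCConfig(
                    n_equilibration_sweeps=config.n_equilibration_sweeps,
                    n_production_sweeps=config.n_production_sweeps,
                    thinning=config.thinning,
                    seed=config.seed,
                )
                ensembles = mc.salt_scan(
                    seq, eparams, config.salts_mM, cfg,
                    scheme=scheme, restraint_pairs=use_pairs,
                )
                for salt, ens in ensembles.items():
                    stem = seq_dir / f"salt{salt:g}_{mode}"
                    npz = stem.with_suffix(".npz")
                    ens.save_npz(npz)
                    summary = analysis.summary_json(
                        ens, stem.parent / (stem.name + "_summary.json")
                    )
                    runs[(salt, mode)] = {
                        "ensemble": str(npz),
                        "summary": str(stem.parent / (stem.name + "_summary.json")),
                        "mean_Rg": summary["mean_Rg"],
                    }
                    artifacts += [npz, stem.parent / (stem.name + "_summary.json")]
            bundle["sequences"][seq.id] = {
                "length": len(seq),
                "profile_csv": str(prof_csv),
                "census_json": str(census_json),
                "net_charge": census.net,
                "runs": {f"{salt:g}|{mode}": v for (salt, mode), v in runs.items()},
            }
    except Exception as exc:
        qdir = outdir / "quarantine"
        qdir.mkdir(exist_ok=True)
        (qdir / "error_manifest.json").write_text(
            json.dumps(
                {"error": str(exc), "traceback": traceback.format_exc()}, indent=2
            )
        )
        raise

    manifest = {
        "seed": config.seed,
        "artifacts": {str(p): _sha256(p) for p in artifacts if p.exists()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = str(manifest_path)
    return bundle


def report(bundle: dict) -> pd.DataFrame:
    """Human-readable summary table from a completed bundle.

    One row per sequence × salt × restraint mode with mean_Rg, var_Rg,
    ν and R_shape; per sequence the maximum relative Rg spread across
    salts flags salt sensitivity, and with/without restraint pairs are
    reduced to ΔRg columns.
    """
    if not bundle.get("sequences"):
        raise ValueError("empty bundle: no sequence stages present")
    rows = []
    for seq_id, info in bundle["sequences"].items():
        if not info.get("runs"):
            raise ValueError(f"bundle for {seq_id!r} lacks simulation outputs")
        for key, run in info["runs"].items():
            salt_s, mode = key.split("|")
            summary = json.loads(Path(run["summary"]).read_text())
            rows.append(
                {
                    "sequence": seq_id,
                    "salt_mM": float(salt_s),
                    "restraints": mode,
                    "mean_Rg": summary["mean_Rg"],
                    "var_Rg": summary["var_Rg"],
                    "nu": summary["nu"],
                    "R_shape": summary["R_shape"],
                }
            )
    df = pd.DataFrame(rows)
    spreads = (
        df.groupby(["sequence", "restraints"])["mean_Rg"]
        .agg(lambda s: (s.max() - s.min()) / s.mean())
        .rename("salt_Rg_spread")
    )
    df = df.merge(spreads, on=["sequence", "restraints"])
    pivot = df.pivot_table(
        index=["sequence", "salt_mM"], columns="restraints",
        values=["mean_Rg", "var_Rg"],
    )
    if ("mean_Rg", "with") in pivot.columns and ("mean_Rg", "without") in pivot.columns:
        delta = pd.DataFrame(
            {
                "delta_mean_Rg": pivot[("mean_Rg", "with")]
                - pivot[("mean_Rg", "without")],
                "delta_var_Rg": pivot[("var_Rg", "with")]
                - pivot[("var_Rg", "without")],
            }
        ).reset_index()
        df = df.merge(delta, on=["sequence", "salt_mM"], how="left")
    return df
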