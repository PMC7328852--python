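"""Study-level analysis: run every modality over a generated (or real) study.

These helpers consume the ``manifest.csv`` layout written by
:func:`chemoassay.synthetic_data.generate_study` and produce tidy
per-sample result tables ready for :mod:`chemoassay.stats_report`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from chemoassay import io as cio
from chemoassay import llct_visco, clsm_quant, oct_quant

__all__ = [
    "load_manifest",
    "analyze_oct_study",
    "analyze_llct_study",
    "analyze_clsm_study",
    "analyze_study",
]


def load_manifest(study_dir: str | Path) -> pd.DataFrame:
    study_dir = Path(study_dir)
    manifest = pd.read_csv(study_dir / "manifest.csv")
    manifest.attrs["study_dir"] = study_dir
    return manifest


def analyze_oct_study(manifest: pd.DataFrame,
                      shared_thresholds: bool = True) -> pd.DataFrame:
    """Dissolution/disruption percentages for every pre/post scan pair."""
    study_dir = Path(manifest.attrs["study_dir"])
    rows = []
    for _, r in manifest.iterrows():
        pre = cio.read_bscan(study_dir / r["oct_pre"])
        post = cio.read_bscan(study_dir / r["oct_post"])
        m = oct_quant.analyze_pair(pre, post, shared_thresholds=shared_thresholds)
        pre_h = oct_quant.column_heights(oct_quant.segment_layers(pre), pre)
        rows.append({
            "sample_id": r["sample_id"],
            "time_s": r["time_s"], "volume_ul": r["volume_ul"],
            "dissolution_pct": m.dissolution_pct,
            "disruption_pct": m.disruption_pct,
            "pre_mean_coherent_um": pre_h.mean_coherent_um,
            "pre_mean_disrupted_um": pre_h.mean_disrupted_um,
        })
    return pd.DataFrame(rows)


def analyze_llct_study(manifest: pd.DataFrame, strain: float = 0.2,
                       restarts: int = 8, seed: int = 0) -> pd.DataFrame:
    """R, fitted Maxwell parameters and component importances per sample."""
    study_dir = Path(manifest.attrs["study_dir"])
    rows = []
    for _, r in manifest.iterrows():
        record = cio.read_relaxation_csv(study_dir / r["relaxation"], strain=strain)
        ref_path = study_dir / r["evaporation_ref"]
        if ref_path.exists():
            record = llct_visco.correct_evaporation(
                record, cio.read_reference_csv(ref_path))
        model = llct_visco.fit_maxwell(record, restarts=restarts, seed=seed)
        imp = llct_visco.relative_importance(model).as_dict()
        row = {
            "sample_id": r["sample_id"],
            "time_s": r["time_s"], "volume_ul": r["volume_ul"],
            "R_pct": llct_visco.stress_relaxation_pct(record),
            "sse": model.sse,
        }
        row.update({f"E{k + 1}_pa": float(model.E[k]) for k in range(4)})
        row.update({f"tau{k + 1}_s": float(model.tau[k]) for k in range(4)})
        row.update({f"pct_{name}": v for name, v in imp.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_clsm_study(manifest: pd.DataFrame) -> pd.DataFrame:
    """Live/dead/EPS biovolume fractions per sample."""
    study_dir = Path(manifest.attrs["study_dir"])
    rows = []
    for _, r in manifest.iterrows():
        stack = cio.read_clsm_stack(study_dir / r["clsm"])
        frac = clsm_quant.component_fractions(stack)
        rows.append({
            "sample_id": r["sample_id"],
            "time_s": r["time_s"], "volume_ul": r["volume_ul"],
            "pct_live": frac.pct_live, "pct_dead": frac.pct_dead,
            "pct_eps": frac.pct_eps,
            "biovolume_live_um3": frac.biovolume_um3[0],
            "biovolume_dead_um3": frac.biovolume_um3[1],
            "biovolume_eps_um3": frac.biovolume_um3[2],
        })
    return pd.DataFrame(rows)


def analyze_study(study_dir: str | Path, **llct_kwargs) -> pd.DataFrame:
    """All three modalities joined into one per-sample results table."""
    manifest = load_manifest(study_dir)
    keys = ["sample_id", "time_s", "volume_ul"]
    oct_res = analyze_oct_study(manifest)
    llct_res = analyze_llct_study(manifest, **llct_kwargs)
    clsm_res = analyze_clsm_study(manifest)
    out = oct_res.merge(llct_res, on=keys).merge(clsm_res, on=keys)
    return out
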