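"""End-to-end run: simulate -> measure -> stats -> report.

``run_pipeline`` executes the whole chain under one seed and writes every
intermediate table, a combined statistics report and a run log; rerunning
with the same config and seed reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, coc_expansion, endpoint_stats, io, mito_profile
from . import nucleus_cytometry as cyto
from . import synthgen
from .config import RunConfig
from .datasets import load_counts

#: Per-group MII probabilities used when simulating a nuclear-maturation
#: screen (proportions of the bundled DES example screen).
DEFAULT_MII_PROBS = {
    "control": (0.80, 0.20),
    "vehicle": (0.84, 0.16),
    "DES 1e-9 M": (0.82, 0.18),
    "DES 1e-7 M": (0.80, 0.20),
    "DES 1e-5 M": (0.03, 0.97),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a bundle of output paths and key numbers."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)

    # -- simulate + measure: mitochondrial distribution -------------------
    mito_rows = []
    for i in range(config.n_oocytes):
        scene, truth = synthgen.make_oocyte_scene(
            radius_px=config.oocyte_radius_px,
            true_ratio=config.oocyte_true_ratio,
            noise_sd=config.oocyte_noise_sd,
            n_z=5,
            seed=seed + i,
        )
        profile, seg = mito_profile.profile_scene(
            scene, config.center_fraction, config.aggregate_planes
        )
        mito_rows.append(
            {
                "oocyte_id": f"oocyte_{i}",
                "plane_index": seg.plane_index,
                "center_mean": profile.center_mean,
                "cortex_mean": profile.cortex_mean,
                "ratio": profile.relative_peripheral_intensity,
                "true_ratio": truth.true_ratio,
            }
        )
    mito_df = pd.DataFrame(mito_rows)
    mito_df.to_csv(out / "mito_profiles.csv", index=False)

    # -- simulate + measure: cumulus expansion ----------------------------
    records = []
    for i in range(config.n_expansion_pairs):
        (before, after), truth = synthgen.make_expansion_pair(
            area_before_px=12000, fold=config.expansion_fold, irregularity=0.3,
            seed=seed + 100 + i,
        )
        _, a_before = coc_expansion.segment_coc_area(before.plane("brightfield"))
        _, a_after = coc_expansion.segment_coc_area(after.plane("brightfield"))
        records.append(
            coc_expansion.ExpansionRecord(f"coc_{i}", a_before, a_after)
        )
    expansion_df = coc_expansion.records_to_frame(records)
    expansion_df.to_csv(out / "expansion_records.csv", index=False)

    # -- simulate + measure: nucleus cytometry ----------------------------
    cyto_rows = []
    nucleus_tables = []
    for i in range(config.n_nucleus_fields):
        n = config.nuclei_per_field
        n_apop = max(1, round(0.03 * n))
        n_sec = max(1, round(0.04 * n))
        scene, truth = synthgen.make_coc_nucleus_scene(
            n_total=n, n_tunel_only=n_apop, n_ethd1_only=0, n_double=n_sec,
            noise_sd=8.0, seed=seed + 200 + i,
            frame=(config.nucleus_frame_px, config.nucleus_frame_px),
        )
        rates, table = cyto.analyze_coc_scene(
            scene,
            n_planes=config.n_planes,
            bg_radius_px=config.bg_radius_px,
            overlap_min=config.overlap_min,
            size_min_px=config.size_min_px,
            size_max_px=config.size_max_px,
            coc_id=f"coc_{i}",
        )
        table.insert(0, "scene_id", f"coc_{i}")
        nucleus_tables.append(table)
        cyto_rows.append(
            {
                "coc_id": rates.coc_id,
                "n_total": rates.n_total,
                "n_apoptotic": rates.n_apoptotic,
                "n_necrotic": rates.n_necrotic,
                "n_secondary": rates.n_secondary,
                "apoptotic_rate": rates.apoptotic_rate,
                "necrotic_rate": rates.necrotic_rate,
            }
        )
    pd.concat(nucleus_tables, ignore_index=True).to_csv(
        out / "nucleus_tables.csv", index=False
    )
    pd.DataFrame(cyto_rows).to_csv(out / "coc_cytometry.csv", index=False)

    # -- stats: contingency endpoint --------------------------------------
    if config.counts_csv:
        counts = io.read_counts(config.counts_csv)
    else:
        counts = synthgen.simulate_experiment_counts(
            {g: list(p) for g, p in DEFAULT_MII_PROBS.items()},
            n_per_group=90,
            categories=["MII", "abnormal"],
            seed=seed + 300,
        )
    io.write_counts(counts, out / "simulated_counts.csv")
    rates_df = endpoint_stats.derive_rates(counts, kind="meiotic")
    rates_df.to_csv(out / "maturation_rates.csv", index=False)
    chi = endpoint_stats.contingency_chi_square(counts, alpha=config.alpha)
    chi.pairwise = endpoint_stats.posthoc_proportion_ztests(
        counts, counts.columns[0], comparisons=config.comparisons,
        reference=config.reference_group, alpha=config.alpha,
    )

    # -- stats: steroid endpoint ------------------------------------------
    if config.values_csv:
        grouped = io.read_values(config.values_csv)
        steroid_reports = {"values": endpoint_stats.anova_tukey(grouped, config.alpha)}
    else:
        steroids = synthgen.simulate_steroid_table(seed=seed + 400)
        steroids.to_csv(out / "steroid_table.csv", index=False)
        steroid_reports = {}
        for analyte, sub in steroids.groupby("analyte", sort=False):
            grouped = {
                g: s["concentration_ng_ml"].to_numpy()
                for g, s in sub.groupby("group", sort=False)
            }
            steroid_reports[analyte] = endpoint_stats.anova_tukey(grouped, config.alpha)

    # -- stats: necrotic-rate endpoint (nonparametric) --------------------
    cyto_df = pd.DataFrame(cyto_rows)
    reports = {"nuclear_maturation_chi_square": chi}
    reports.update({f"steroid_{k}": v for k, v in steroid_reports.items()})
    io.write_report(reports, out / "stat_report.json")

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "effective_config": config.to_dict(),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))

    return {
        "out_dir": str(out),
        "mito_mean_ratio": float(mito_df["ratio"].mean()),
        "expansion_mean_fold": float(expansion_df["fold_increase"].mean()),
        "cytometry": cyto_df.to_dict("records"),
        "reports": {k: v.to_dict() for k, v in reports.items()},
    }


def analyze_bundled_screen(alpha: float = 0.05) -> dict:
    """Contingency statistics for every bundled endpoint table."""
    out = {}
    for name in ("nuclear_maturation", "cleavage_ivm_exposure", "cleavage_ivc_exposure"):
        counts = load_counts(name)
        report = endpoint_stats.contingency_chi_square(counts, alpha=alpha)
        report.pairwise = endpoint_stats.posthoc_proportion_ztests(
            counts, counts.columns[0], comparisons="all-pairs", alpha=alpha
        )
        out[name] = {
            "counts": counts,
            "rates": endpoint_stats.derive_rates(
                counts, "meiotic" if name == "nuclear_maturation" else "cleavage"
            ),
            "report": report,
        }
    return out
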