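"""End-to-end orchestration: preprocess -> power -> PSI -> networks -> stats."""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .epochs import EpochSet
from .groupstats import (
    degree_tmap,
    mixed_anova,
    multi_density_rule,
    paired_t,
    relative_change,
    roi_mean_degree,
    welch_t,
)
from .montage import Montage
from .network import density_sweep, node_degree, threshold_graph
from .phasesync import PSIMatrix, psi_matrix
from .preprocess import (
    bandpass_filter,
    extract_window,
    reject_artifacts,
    rereference,
    subtract_all_erps,
)
from .spectral import band_power, percent_change

logger = logging.getLogger("synchnet")


@dataclass
class SubjectResult:
    subject: str
    group: str | None
    n_epochs_in: int
    n_epochs_kept: int
    rejection_report: pd.DataFrame
    psi_matrices: dict[tuple[str, str], PSIMatrix]  # (condition, band) -> PSI
    band_power: pd.DataFrame
    network_metrics: pd.DataFrame
    roi_degree: pd.DataFrame


@dataclass
class PipelineResult:
    subjects: list[SubjectResult]
    network_metrics: pd.DataFrame
    band_power: pd.DataFrame
    percent_change: pd.DataFrame | None
    roi_degree: pd.DataFrame
    anova: pd.DataFrame | None
    density_rule: pd.DataFrame | None
    roi_contrasts: pd.DataFrame | None
    tmaps: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def process_subject(
    epochs: EpochSet,
    config: PipelineConfig,
    montage: Montage | None = None,
    seed: np.random.SeedSequence | None = None,
) -> SubjectResult:
    """Run all per-subject stages on one epoch set."""
    seed = seed if seed is not None else np.random.SeedSequence(config.seed)
    n_in = epochs.n_epochs
    conditions_in = epochs.condition_labels()

    filtered = bandpass_filter(epochs, config.filter)
    logger.info("%s: filtered %d epochs (%s)", epochs.subject, n_in, config.filter)

    refs = tuple(montage.references) if montage is not None else ()
    if refs and all(r in filtered.channels for r in refs):
        filtered = rereference(filtered, refs)
        logger.info(
            "%s: re-referenced to %s, %d channels kept",
            epochs.subject, refs, filtered.n_channels,
        )

    kept, report = reject_artifacts(filtered, config.artifact)
    logger.info(
        "%s: artifact rejection kept %d/%d epochs (%d violations)",
        epochs.subject, kept.n_epochs, n_in, len(report),
    )
    for cond in conditions_in:
        if not (kept.conditions == cond).any():
            raise ValueError(
                f"all epochs of condition {cond!r} rejected for {epochs.subject}"
            )

    induced, _ = subtract_all_erps(kept, config.erp_subtract_conditions)

    power = band_power(
        induced, config.analysis_window_ms, config.bands
    )

    bands = {name: (lo, hi) for name, lo, hi in config.bands}
    psi_matrices: dict[tuple[str, str], PSIMatrix] = {}
    net_rows = []
    roi_rows = []
    n_pairs = induced.n_channels * (induced.n_channels - 1) // 2
    k_sweep = tuple(k for k in config.k_sweep if k <= n_pairs)
    for cond in induced.condition_labels():
        for band_name, edges in bands.items():
            child = np.random.SeedSequence(
                entropy=seed.entropy,
                spawn_key=tuple(seed.spawn_key)
                + (zlib.crc32(f"{cond}/{band_name}".encode()),),
            )
            mat = psi_matrix(
                induced,
                band=edges,
                band_name=band_name,
                condition=cond,
                window_ms=config.analysis_window_ms,
                filter_order=config.band_filter_order,
            )
            psi_matrices[(cond, band_name)] = mat
            summaries = density_sweep(
                mat,
                k_sweep,
                n_random=config.n_random_networks,
                seed=child,
                clustering_mode=config.clustering_mode,
                path_mode=config.path_length_mode,
            )
            for s in summaries:
                net_rows.append(
                    {
                        "subject": induced.subject,
                        "group": induced.group,
                        "condition": cond,
                        "band": band_name,
                        "K": s.k,
                        "density": s.density,
                        "C": s.clustering,
                        "L": s.path_length,
                        "C_rand": s.c_rand,
                        "L_rand": s.l_rand,
                        "gamma": s.gamma,
                        "lambda": s.lambda_,
                        "sigma": s.sigma,
                    }
                )
            if config.degree_threshold_k <= n_pairs:
                graph = threshold_graph(mat, config.degree_threshold_k)
                deg = node_degree(graph)
                for ch, d in zip(graph.labels, deg):
                    roi_rows.append(
                        {
                            "subject": induced.subject,
                            "group": induced.group,
                            "condition": cond,
                            "band": band_name,
                            "K": config.degree_threshold_k,
                            "channel": ch,
                            "degree": float(d),
                            "roi": "",
                        }
                    )
                for roi_name, roi_chs in config.rois.items():
                    present = [c for c in roi_chs if c in graph.labels]
                    if not present:
                        continue
                    roi_rows.append(
                        {
                            "subject": induced.subject,
                            "group": induced.group,
                            "condition": cond,
                            "band": band_name,
                            "K": config.degree_threshold_k,
                            "channel": "",
                            "degree": roi_mean_degree(deg, graph.labels, present),
                            "roi": roi_name,
                        }
                    )
    logger.info("%s: %d PSI matrices, %d network summaries",
                induced.subject, len(psi_matrices), len(net_rows))
    return SubjectResult(
        subject=induced.subject,
        group=induced.group,
        n_epochs_in=n_in,
        n_epochs_kept=kept.n_epochs,
        rejection_report=report,
        psi_matrices=psi_matrices,
        band_power=power,
        network_metrics=pd.DataFrame(net_rows),
        roi_degree=pd.DataFrame(roi_rows),
    )


def group_statistics(
    metrics: pd.DataFrame,
    roi_degree: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame | None, pd.DataFrame | None, pd.DataFrame | None, pd.DataFrame | None]:
    """ANOVA tables, multi-density significance, ROI contrasts, degree t-maps."""
    groups = [g for g in metrics["group"].unique() if g is not None]
    has_groups = len(groups) >= 2
    anova_rows = []
    if has_groups:
        for (band, k), sub in metrics.groupby(["band", "K"]):
            for metric in ("gamma", "lambda", "sigma"):
                table = sub.rename(columns={metric: "value"})[
                    ["subject", "group", "condition", "value"]
                ]
                sizes = table.groupby("group")["subject"].nunique()
                if (sizes < 2).any():
                    continue
                try:
                    results = mixed_anova(table)
                except ValueError:
                    continue
                for r in results:
                    anova_rows.append(
                        {
                            "band": band,
                            "K": k,
                            "metric": metric,
                            "effect": r.effect,
                            "F": r.statistic,
                            "df1": r.df[0],
                            "df2": r.df[1],
                            "p": r.p_value,
                        }
                    )
    anova = pd.DataFrame(anova_rows) if anova_rows else None

    rule = None
    if anova is not None and len(anova):
        rule_rows = []
        for (band, metric, effect), sub in anova.groupby(["band", "metric", "effect"]):
            ps = sub.sort_values("K")["p"].tolist()
            rule_rows.append(
                {
                    "band": band,
                    "metric": metric,
                    "effect": effect,
                    "n_levels": len(ps),
                    "n_significant": sum(p < config.alpha for p in ps),
                    "significant": multi_density_rule(
                        ps, config.alpha, config.min_significant_levels
                    ),
                }
            )
        rule = pd.DataFrame(rule_rows)

    contrast_rows = []
    roi_only = roi_degree[roi_degree["roi"] != ""]
    conds = set(roi_degree["condition"].unique())
    if {"Go", "NoGo"} <= conds and len(roi_only):
        for (band, roi), sub in roi_only.groupby(["band", "roi"]):
            wide = sub.pivot_table(
                index=["subject", "group"], columns="condition", values="degree"
            ).reset_index()
            rel = {}
            for grp, gsub in wide.groupby("group"):
                go = gsub["Go"].to_numpy()
                nogo = gsub["NoGo"].to_numpy()
                if len(go) >= 2:
                    try:
                        res = paired_t(go, nogo, effect=f"{band}/{roi} Go-NoGo")
                        contrast_rows.append(
                            {
                                "band": band, "roi": roi, "group": grp,
                                "test": "paired_t", "statistic": res.statistic,
                                "df": res.df, "p": res.p_value,
                            }
                        )
                    except ValueError:
                        pass
                rel[grp] = [
                    relative_change(a, b, config.relative_change_mode)
                    for a, b in zip(go, nogo)
                    if (a + b) != 0
                ]
            if has_groups and all(len(rel.get(g, [])) >= 2 for g in groups[:2]):
                try:
                    res = welch_t(
                        rel[groups[0]], rel[groups[1]],
                        effect=f"{band}/{roi} relative change",
                    )
                    contrast_rows.append(
                        {
                            "band": band, "roi": roi,
                            "group": f"{groups[0]} vs {groups[1]}",
                            "test": "welch_t", "statistic": res.statistic,
                            "df": res.df, "p": res.p_value,
                        }
                    )
                except ValueError:
                    pass
    contrasts = pd.DataFrame(contrast_rows) if contrast_rows else None

    tmap_rows = []
    chan_deg = roi_degree[roi_degree["channel"] != ""]
    if {"Go", "NoGo"} <= conds and len(chan_deg):
        for (band, grp), sub in chan_deg.groupby(["band", "group"], dropna=False):
            if sub["subject"].nunique() < 2:
                continue
            tmap = degree_tmap(sub, ("NoGo", "Go"))
            tmap["band"] = band
            tmap["group"] = grp
            tmap_rows.append(tmap)
    tmaps = pd.concat(tmap_rows, ignore_index=True) if tmap_rows else None
    return anova, rule, contrasts, tmaps


def run_pipeline(
    config: PipelineConfig,
    epoch_sets: list[EpochSet],
    montage: Montage | None = None,
) -> PipelineResult:
    """Full analysis over a list of per-subject epoch sets.

    Deterministic for fixed (inputs, config, config.seed).
    """
    if not epoch_sets:
        raise ValueError("no input epoch sets")
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(len(epoch_sets))
    subjects = [
        process_subject(es, config, montage, seed)
        for es, seed in zip(epoch_sets, subject_seeds)
    ]

    metrics = pd.concat([s.network_metrics for s in subjects], ignore_index=True)
    power = pd.concat([s.band_power for s in subjects], ignore_index=True)
    roi = pd.concat([s.roi_degree for s in subjects], ignore_index=True)

    pct = None
    if "Baseline" in set(power["condition"]):
        pieces = []
        base = power[power["condition"] == "Baseline"]
        for cond in sorted(set(power["condition"]) - {"Baseline"}):
            pieces.append(percent_change(power[power["condition"] == cond], base))
        pct = pd.concat(pieces, ignore_index=True) if pieces else None

    anova, rule, contrasts, tmaps = group_statistics(metrics, roi, config)
    manifest = {
        "n_subjects": len(subjects),
        "epochs_in": int(sum(s.n_epochs_in for s in subjects)),
        "epochs_kept": int(sum(s.n_epochs_kept for s in subjects)),
        "bands": [b[0] for b in config.bands],
        "k_sweep": list(config.k_sweep),
        "seed": config.seed,
    }
    return PipelineResult(
        subjects=subjects,
        network_metrics=metrics,
        band_power=power,
        percent_change=pct,
        roi_degree=roi,
        anova=anova,
        density_rule=rule,
        roi_contrasts=contrasts,
        tmaps=tmaps,
        manifest=manifest,
    )
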