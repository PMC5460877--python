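"""Per-species orchestration and cross-species report tables.

``run_species`` composes the whole per-species analysis — preference
calling, polarization, descriptive codon-usage statistics, skewness and
MK-style summary statistics, the separate and joint spectrum-model fits,
and the gene-category stratifications — into a bundle of deterministic
TSV reports.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .alignments import extract_changes, read_alignments
from .codonbias import (
    CodonPreferenceCaller,
    enc,
    fop,
    gc3,
    gc3_expression_correlation,
    pi_stats,
)
from .sfsmodel import JointModelScan, fit_sfs_model, nested_force_tests
from .spectra import (
    build_sfs,
    dos,
    gc_allele_frequencies,
    preferred_allele_frequencies,
    mk_chi2,
    mk_table,
    ni,
    binned_mk,
    crossed_mk,
    skewness,
    skewness_test,
    split_first_part,
    write_sfs_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one per-species run."""

    species: str = "species"
    alignment_dir: str | None = None
    expression_path: str | None = None
    out_dir: str = "gcforces_out"
    selfing: bool = False
    first_part_cutoff: int = 252
    k_bins: int = 8
    alpha: float = 0.05
    seed: int = 0
    n_starts: int = 3
    compute_ci: bool = True
    fit_joint: bool = True
    n_boot: int = 2000
    group: str = ""  # taxonomic group label for cross-species tests
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        return cfg


def _fit_row(set_name: str, fr) -> dict:
    f0, f1 = ("B0", "B1") if set_name == "gBGC" else ("S0", "S1")
    ci = fr.conf_int
    row = {
        "set": set_name,
        "lambda": fr.estimates["lambda"],
        "lambda_ci_low": ci.get("lambda", (np.nan, np.nan))[0],
        "lambda_ci_high": ci.get("lambda", (np.nan, np.nan))[1],
        "ancestral": fr.estimates[f0],
        "ancestral_ci_low": ci.get(f0, (np.nan, np.nan))[0],
        "ancestral_ci_high": ci.get(f0, (np.nan, np.nan))[1],
        "recent": fr.estimates[f1],
        "recent_ci_low": ci.get(f1, (np.nan, np.nan))[0],
        "recent_ci_high": ci.get(f1, (np.nan, np.nan))[1],
        "p_ancestral_0": fr.lrt_pvalues.get("ancestral=0", np.nan),
        "p_recent_0": fr.lrt_pvalues.get("recent=0", np.nan),
        "p_recent_ancestral": fr.lrt_pvalues.get("recent=ancestral", np.nan),
        "e": fr.estimates["e"],
        "loglik": fr.loglik,
        "aic": fr.aic,
    }
    return row


def _summary_row(label, freqs, table, n_boot, seed):
    row = {"set": label, "n_snps": len(freqs)}
    if len(freqs) >= 10 and np.var(freqs) > 0:
        row["mean_freq"] = float(np.mean(freqs))
        row["skewness"] = skewness(freqs)
        row["skewness_p"] = skewness_test(freqs, n_boot=n_boot, seed=seed)
    else:
        row.update(mean_freq=np.nan, skewness=np.nan, skewness_p=np.nan)
    row["ni"] = ni(table)
    row["dos"] = dos(table)
    try:
        row["mk_p"] = mk_chi2(table)
    except ValueError:
        row["mk_p"] = np.nan
    for name, v in zip(("p_fwd", "p_rev", "d_fwd", "d_rev"),
                       (table.p_ws, table.p_sw, table.d_ws, table.d_sw)):
        row[name] = v
    return row


def run_species(config: PipelineConfig, alignments=None, expression=None) -> dict:
    """Run the full per-species analysis; returns the report bundle.

    ``alignments``/``expression`` may be passed directly (e.g. from the
    synthetic generator); otherwise they are read from the configured paths.
    Writes all report TSVs plus a run log under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    if alignments is None:
        if config.alignment_dir is None:
            raise ValueError("no alignments given and no alignment_dir configured")
        paths = sorted(
            os.path.join(config.alignment_dir, p)
            for p in os.listdir(config.alignment_dir)
            if p.endswith((".fasta", ".fa"))
        )
        alignments = read_alignments(paths)
    if expression is None and config.expression_path:
        expression = pd.read_csv(
            config.expression_path, sep="\t", index_col="contig_id"
        )["rpkm"]

    consensus = {a.contig_id: a.consensus() for a in alignments}
    start_contigs = {a.contig_id for a in alignments if a.has_start_codon}

    # --- codon preferences -------------------------------------------------
    prefs = None
    pref_table = pd.DataFrame()
    if expression is not None:
        caller = CodonPreferenceCaller(k_bins=config.k_bins, alpha=config.alpha)
        try:
            prefs = caller.fit(consensus, expression.to_dict())
            pref_table = caller.table_.reset_index()
        except ValueError as exc:
            logger.warning("preference calling skipped: %s", exc)
    else:
        logger.warning("no expression table: preference calling skipped")

    # --- polarization ------------------------------------------------------
    changes = extract_changes(
        alignments,
        prefs=prefs,
        first_part_cutoff=config.first_part_cutoff,
        selfing=config.selfing,
        seed=config.seed,
    )

    # --- per-gene metrics --------------------------------------------------
    rows = []
    for aln in alignments:
        seq = consensus[aln.contig_id]
        try:
            g3 = gc3(seq)
        except ValueError:
            g3 = np.nan
        pi_s, pi_n = pi_stats(aln)
        rows.append(
            {
                "contig_id": aln.contig_id,
                "gc3": g3,
                "enc": enc(seq),
                "fop": fop(seq, prefs) if prefs is not None else np.nan,
                "pi_s": pi_s,
                "pi_n": pi_n,
            }
        )
    metrics = pd.DataFrame(rows).set_index("contig_id")
    descriptive = {
        "species": config.species,
        "n_contigs": len(alignments),
        "n_changes": len(changes),
        "n_snps": int((changes["kind"] == "SNP").sum()),
        "gc3_mean": float(metrics["gc3"].mean()),
        "enc_mean": float(metrics["enc"].mean()),
        "pi_s_mean": float(np.nanmean(metrics["pi_s"])),
        "pi_n_mean": float(np.nanmean(metrics["pi_n"])),
    }
    if expression is not None:
        try:
            descriptive["cor_gc3_expression"] = gc3_expression_correlation(
                metrics["gc3"].reindex(expression.index),
                expression.reindex(expression.index),
            )
        except ValueError:
            descriptive["cor_gc3_expression"] = np.nan
    if prefs is not None:
        descriptive["n_pref_gc"] = prefs.n_pref_gc_
        descriptive["n_pref_at"] = prefs.n_pref_at_

    # --- summary statistics (skewness / NI / DoS) --------------------------
    summary_rows = [
        _summary_row(
            "gBGC", gc_allele_frequencies(changes), mk_table(changes, "gBGC"),
            config.n_boot, config.seed,
        )
    ]
    if prefs is not None:
        summary_rows.append(
            _summary_row(
                "SCU", preferred_allele_frequencies(changes),
                mk_table(changes, "SCU"), config.n_boot, config.seed,
            )
        )
    summary = pd.DataFrame(summary_rows)

    # --- spectra and model fits -------------------------------------------
    sfs_gbgc = build_sfs(changes, "gBGC")
    write_sfs_table(sfs_gbgc, os.path.join(config.out_dir, "sfs_gbgc.tsv"))
    fit_kwargs = dict(
        n_starts=config.n_starts, seed=config.seed, compute_ci=config.compute_ci
    )
    fit_rows = [_fit_row("gBGC", nested_force_tests(sfs_gbgc, **fit_kwargs))]
    if prefs is not None:
        sfs_scu = build_sfs(changes, "SCU")
        write_sfs_table(sfs_scu, os.path.join(config.out_dir, "sfs_scu.tsv"))
        fit_rows.append(_fit_row("SCU", nested_force_tests(sfs_scu, **fit_kwargs)))
    fits = pd.DataFrame(fit_rows)

    joint_best = pd.DataFrame()
    if config.fit_joint and prefs is not None:
        sfs_joint = build_sfs(changes, "joint")
        scan = JointModelScan(
            n_starts=max(1, config.n_starts // 2), seed=config.seed
        ).fit(sfs_joint)
        joint_best = pd.DataFrame(
            [
                {
                    "species": config.species,
                    "model": scan.best_label_,
                    "co_best": ";".join(scan.co_best_),
                    "B0": scan.best_.estimates.get("B0", 0.0),
                    "B1": scan.best_.estimates.get("B1", 0.0),
                    "S0": scan.best_.estimates.get("S0", 0.0),
                    "S1": scan.best_.estimates.get("S1", 0.0),
                    "aic": scan.best_.aic,
                }
            ]
        )
        scan.scan_.to_csv(
            os.path.join(config.out_dir, "joint_model_scan.tsv"), sep="\t", index=False
        )

    # --- stratifications ---------------------------------------------------
    binned = {}
    if len(changes):
        binned["gc3"] = binned_mk(changes, metrics["gc3"], k=config.k_bins)
        if expression is not None:
            expr = expression.reindex(metrics.index).fillna(0.0)
            binned["expression"] = binned_mk(
                changes, expr, k=config.k_bins,
                set_name="SCU" if prefs is not None else "gBGC",
            )
            binned["crossed"] = crossed_mk(changes, metrics["gc3"], expr)

    first, rest = split_first_part(
        changes, cutoff=config.first_part_cutoff, require_start=True,
        start_contigs=start_contigs,
    )
    first_rows = []
    for label, sub in (("first", first), ("rest", rest)):
        data = build_sfs(sub, "gBGC")
        fr = fit_sfs_model(
            data, b0="free", b1="equal", n_starts=config.n_starts,
            seed=config.seed, compute_ci=config.compute_ci,
        )
        t = mk_table(sub, "gBGC")
        first_rows.append(
            {
                "part": label,
                "n_changes": len(sub),
                "B": fr.estimates["B0"],
                "B_ci_low": fr.conf_int.get("B0", (np.nan, np.nan))[0],
                "B_ci_high": fr.conf_int.get("B0", (np.nan, np.nan))[1],
                "lambda": fr.estimates["lambda"],
                "ni": ni(t),
                "dos": dos(t),
            }
        )
    first_part = pd.DataFrame(first_rows)

    # --- outputs -----------------------------------------------------------
    out = config.out_dir
    pd.DataFrame([descriptive]).to_csv(
        os.path.join(out, "descriptive_stats.tsv"), sep="\t", index=False
    )
    metrics.to_csv(os.path.join(out, "gene_metrics.tsv"), sep="\t")
    pref_table.to_csv(os.path.join(out, "codon_preferences.tsv"), sep="\t", index=False)
    summary.to_csv(os.path.join(out, "summary_stats.tsv"), sep="\t", index=False)
    fits.to_csv(os.path.join(out, "model_fits.tsv"), sep="\t", index=False)
    joint_best.to_csv(os.path.join(out, "joint_best_model.tsv"), sep="\t", index=False)
    for name, df in binned.items():
        df.to_csv(os.path.join(out, f"binned_{name}.tsv"), sep="\t", index=False)
    first_part.to_csv(os.path.join(out, "first_part.tsv"), sep="\t", index=False)
    changes.to_csv(os.path.join(out, "changes.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "run_log.txt"), "w") as fh:
        fh.write(f"gcforces {__version__}\n")
        for k, v in vars(config).items():
            fh.write(f"{k}: {v}\n")

    return {
        "descriptive": pd.DataFrame([descriptive]),
        "metrics": metrics,
        "preferences": pref_table,
        "summary": summary,
        "fits": fits,
        "joint_best": joint_best,
        "binned": binned,
        "first_part": first_part,
        "changes": changes,
    }


def cross_species_report(bundles: pd.DataFrame) -> pd.DataFrame:
    """Cross-species correlations and group comparisons.

    ``bundles`` has one row per species with at least columns ``species``,
    ``B`` (a constant-B estimate) and ``gc3``; optional ``b_first`` /
    ``b_rest`` and a boolean ``group`` column (e.g. Commelinid membership)
    trigger the corresponding extra tests.  Requires at least 3 species for
    correlations.
    """
    rows = []
    if len(bundles) >= 3:
        for col, label in (("B", "overall"), ("b_first", "first_part"), ("b_rest", "rest")):
            if col in bundles:
                rho, p = sps.spearmanr(bundles[col], bundles["gc3"])
                rows.append(
                    {"test": f"spearman_B_gc3_{label}", "statistic": float(rho), "p_value": float(p)}
                )
    if "group" in bundles and bundles["group"].nunique() == 2:
        for col in ("B", "b_first", "b_rest"):
            if col in bundles:
                g = bundles["group"].astype(bool)
                u, p = sps.mannwhitneyu(
                    bundles.loc[g, col], bundles.loc[~g, col], alternative="two-sided"
                )
                rows.append(
                    {"test": f"ranksum_group_{col}", "statistic": float(u), "p_value": float(p)}
                )
    return pd.DataFrame(rows)
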