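"""End-to-end orchestration: QC -> cell adjust -> variability -> concordance
-> mQTL discovery/validation -> differential consensus -> enrichment ->
categorization, from a single config with one global seed.

Every stage draws randomness from a named substream derived from the global
seed, so stages are individually reproducible and the whole run is
idempotent. Each stage logs input/output row counts — the audit trail for
how many probes/pairs survive each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import cell_adjust as ca
from . import concordance as cc
from . import differential as dm
from . import enrichment_classify as ec
from . import mqtl as mq
from . import variability as vb
from .data_io import CohortBundle, intersect_probes, qc_filter_probes, write_beta
from .simulate import SimConfig, TruthTable, simulate_cohorts

__all__ = ["RunConfig", "run_all", "stage_seed"]

log = logging.getLogger("methcordance")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """All pipeline thresholds, with defaults matching the analysis design.

    Either ``sim`` (synthetic mode) or pre-built ``bundles`` must be
    supplied. The discovery cohort is named explicitly; every other cohort
    is a validation cohort.
    """

    sim: SimConfig | None = None
    bundles: list[CohortBundle] | None = None
    truth: TruthTable | None = None
    discovery_cohort: str = ""
    reference_profiles: ca.ReferenceProfiles | None = None
    min_rr_informative: float = 0.05
    min_rr_mixture: float = 0.10
    min_rr_mqtl: float = 0.05
    cis_window: int = 5000
    fdr: float = 0.05
    min_effect: float = 0.025
    min_delta: float = 0.05
    min_het: int = 2
    snp_max_missing: float = 0.05
    snp_min_maf: float = 0.05
    snp_hwe_p: float = 1e-3
    n_perm: int = 10_000
    subsample_n: int = 16
    subsample_trials: int = 100
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.bundles is None):
            raise ValueError("provide exactly one of sim or bundles")
        for name, lo, hi in (
            ("fdr", 0.0, 1.0),
            ("min_effect", 0.0, 1.0),
            ("min_delta", 0.0, 1.0),
            ("min_rr_informative", 0.0, 1.0),
            ("min_rr_mixture", 0.0, 1.0),
            ("min_rr_mqtl", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} out of range [{lo}, {hi}]: {v}")
        if self.cis_window < 1:
            raise ValueError("cis_window must be positive")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(out_dir: Path | None, name: str, obj: Any, manifest: dict[str, str]) -> None:
    if out_dir is None:
        return
    path = out_dir / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", float_format="%.12g")
    elif isinstance(obj, pd.Series):
        obj.to_frame().to_csv(path, sep="\t", float_format="%.12g")
    else:
        path.write_text(json.dumps(obj, indent=2, default=str))
    manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns {"summary": ..., "manifest": ...,
    "tables": ...} and writes all tables plus summary.json when
    ``config.out_dir`` is set. A stage failure raises :class:`StageError`
    naming the stage; partial outputs stay on disk next to a FAILED marker.
    """
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "FAILED").write_text("run incomplete")
    manifest: dict[str, str] = {}
    tables: dict[str, Any] = {}
    summary: dict[str, Any] = {"seed": config.seed}
    stage = "setup"
    try:
        truth = config.truth
        if config.sim is not None:
            stage = "simulate"
            bundles, truth = simulate_cohorts(config.sim)
        else:
            bundles = list(config.bundles)
        names = [b.name for b in bundles]
        discovery = config.discovery_cohort or max(bundles, key=lambda b: b.n_samples).name
        if discovery not in names:
            raise ValueError(f"discovery cohort {discovery!r} not among {names}")
        log.info("cohorts: %s (discovery=%s)", {b.name: b.n_samples for b in bundles}, discovery)

        stage = "probe_qc"
        qc_reports = {}
        filtered = []
        for b in bundles:
            fb, rep = qc_filter_probes(b)
            qc_reports[b.name] = rep.as_dict()
            filtered.append(fb)
            log.info("probe QC %s: %d -> %d probes", b.name, rep.n_input, rep.n_output)
        if len(filtered) > 1:
            filtered = intersect_probes(filtered)
        bundles = {b.name: b for b in filtered}
        n_probes = len(filtered[0].probe_ids)
        summary["n_probes_after_qc"] = n_probes
        summary["probe_qc"] = qc_reports

        stage = "cell_adjust"
        if config.reference_profiles is not None:
            clip_counts = {}
            for name, b in bundles.items():
                for attr in ("beta_a", "beta_b"):
                    beta = getattr(b, attr)
                    props = ca.estimate_proportions(beta, config.reference_profiles)
                    adj, clipped = ca.adjust_composition(beta, props)
                    setattr(b, attr, adj)
                    clip_counts[f"{name}_{beta.tissue or attr}"] = clipped
                    _write(out_dir, f"proportions_{name}_{beta.tissue or attr}.tsv",
                           props.weights, manifest)
            summary["cell_adjust_clipped"] = clip_counts
        else:
            log.info("cell adjustment skipped: no reference profiles supplied")

        stage = "variability"
        summary["variability"] = {}
        var_tables = {}
        for name, b in bundles.items():
            rr_a = vb.reference_range_rows(b.beta_a.values)
            rr_b = vb.reference_range_rows(b.beta_b.values)
            g = vb.global_variability_test(rr_a, rr_b)
            vt = vb.probewise_variance_test(b.beta_a, b.beta_b, fdr=config.fdr)
            var_tables[name] = vt
            more_a = int((vt["more_variable_in"] == (b.beta_a.tissue or "a")).sum())
            more_b = int((vt["more_variable_in"] == (b.beta_b.tissue or "b")).sum())
            summary["variability"][name] = {
                "median_rr_a": float(np.median(rr_a)),
                "median_rr_b": float(np.median(rr_b)),
                "global_wilcoxon_p": g.p_value,
                "median_rr_difference": g.median_difference,
                "n_more_variable_a": more_a,
                "n_more_variable_b": more_b,
            }
            _write(out_dir, f"variability_{name}.tsv", vt, manifest)
            log.info("variability %s: median rr a=%.4f b=%.4f", name,
                     float(np.median(rr_a)), float(np.median(rr_b)))

        stage = "subsample"
        sub = vb.subsample_study(
            bundles[discovery],
            n_sub=min(config.subsample_n, bundles[discovery].n_samples),
            n_trials=config.subsample_trials,
            seed=stage_seed(config.seed, "subsample"),
        )
        tables["subsample"] = sub.table
        _write(out_dir, f"subsample_{discovery}.tsv", sub.table, manifest)

        stage = "concordance"
        informative = {}
        conc_tables = {}
        summary["concordance"] = {}
        for name, b in bundles.items():
            ct = cc.cross_tissue_correlation(b.beta_a, b.beta_b)
            conc_tables[name] = ct
            try:
                fit = cc.fit_rho_mixture(
                    cc.mixture_subset(ct, min_rr=config.min_rr_mixture),
                    seed=stage_seed(config.seed, f"mixture:{name}"),
                )
                flags = cc.call_informative(ct, fit, min_rr=config.min_rr_informative)
                summary["concordance"][name] = {
                    "rho_threshold": fit.threshold,
                    "n_informative": int(flags.sum()),
                }
                _write(out_dir, f"mixture_fit_{name}.json",
                       json.loads(fit.to_json()), manifest)
            except (cc.DegenerateFitError, ValueError) as exc:
                # no separable concordant component: nothing is informative
                log.warning("mixture degenerate in %s (%s); empty informative set", name, exc)
                flags = pd.Series(False, index=ct.index, name="informative")
                summary["concordance"][name] = {
                    "rho_threshold": None,
                    "n_informative": 0,
                    "degenerate_mixture": str(exc),
                }
            informative[name] = flags
            ct_out = ct.assign(informative=flags)
            _write(out_dir, f"concordance_{name}.tsv", ct_out, manifest)
            log.info("concordance %s: informative=%d", name, int(flags.sum()))
        consensus_inf = cc.consensus_informative(informative)
        summary["n_informative_consensus"] = len(consensus_inf)
        tables["informative_consensus"] = consensus_inf
        _write(out_dir, "informative_consensus.tsv",
               pd.Series(consensus_inf, name="probe_id"), manifest)

        stage = "snp_qc"
        geno_ok = {}
        summary["snp_qc"] = {}
        for name, b in bundles.items():
            if b.genotypes is None:
                continue
            g, rep = mq.snp_qc(
                b.genotypes,
                max_missing=config.snp_max_missing,
                min_maf=config.snp_min_maf,
                hwe_p=config.snp_hwe_p,
            )
            geno_ok[name] = g
            summary["snp_qc"][name] = {
                "n_input": int(len(rep.table)),
                "n_pass": int(rep.table["passed"].sum()),
            }
            _write(out_dir, f"snp_qc_{name}.tsv", rep.table, manifest)

        stage = "mqtl"
        validated_by_tissue: dict[str, pd.DataFrame] = {}
        discovery_by_tissue: dict[str, pd.DataFrame] = {}
        if geno_ok:
            db = bundles[discovery]
            pairs = mq.enumerate_cis_pairs(
                db.cpg_manifest, db.snp_manifest, window=config.cis_window
            )
            pairs = pairs[pairs["cpg_id"].isin(db.probe_ids)
                          & pairs["snp_id"].isin(geno_ok[discovery].snp_ids)]
            summary["n_cis_pairs"] = int(len(pairs))
            validation_names = [n for n in bundles if n != discovery]
            summary["mqtl"] = {}
            for attr in ("beta_a", "beta_b"):
                beta_d = getattr(db, attr)
                tname = beta_d.tissue or attr
                rec, unt = mq.scan(
                    beta_d, geno_ok[discovery], pairs,
                    min_rr=config.min_rr_mqtl, fdr=config.fdr,
                    min_effect=config.min_effect, tissue=tname, cohort=discovery,
                )
                discovery_by_tissue[tname] = rec
                hits = rec[rec["hit"]]
                summary["mqtl"][f"discovery_{tname}"] = {
                    "n_tested": int(len(rec)), "n_hits": int(len(hits)),
                }
                _write(out_dir, f"mqtl_discovery_{tname}.tsv", rec, manifest)
                log.info("mQTL discovery %s: %d tested, %d hits", tname, len(rec), len(hits))
                if validation_names:
                    vname = validation_names[0]
                    vbund = bundles[vname]
                    vrec, vrep = mq.validate(
                        hits, getattr(vbund, attr), geno_ok[vname],
                        min_het=config.min_het, min_rr=config.min_rr_mqtl,
                        fdr=config.fdr, min_effect=config.min_effect,
                        tissue=tname, cohort=vname,
                    )
                    validated_by_tissue[tname] = vrec
                    summary["mqtl"][f"validation_{tname}"] = {
                        "n_testable": int(vrep["testable"].sum()),
                        "n_validated": int(vrec["hit"].sum()) if len(vrec) else 0,
                    }
                    _write(out_dir, f"mqtl_validated_{tname}.tsv", vrec, manifest)
            if len(validated_by_tissue) == 2:
                sharing = mq.classify_sharing(validated_by_tissue)
                tables["mqtl_sharing"] = sharing
                summary["mqtl"]["sharing"] = sharing["sharing"].value_counts().to_dict()
                _write(out_dir, "mqtl_sharing.tsv", sharing, manifest)

        stage = "differential"
        diff_tables = {}
        for name, b in bundles.items():
            dt = dm.differential_scan(b.beta_a, b.beta_b,
                                      fdr=config.fdr, min_delta=config.min_delta)
            diff_tables[name] = dt
            _write(out_dir, f"differential_{name}.tsv", dt, manifest)
        # subsampled discovery dataset enters the consensus alongside the cohorts
        db = bundles[discovery]
        mean_a = db.beta_a.values.mean(axis=1)
        mean_b = db.beta_b.values.mean(axis=1)
        # paired signed-rank p averaged over subsampling trials
        sub_p = _subsample_differential_p(
            db, sub_n=sub.n_sub, n_trials=sub.n_trials,
            seed=stage_seed(config.seed, "subsample_diff"),
        )
        diff_tables[f"{discovery}_sub"] = dm.table_from_subsample(
            sub_p, mean_a, mean_b, fdr=config.fdr, min_delta=config.min_delta
        )
        consensus = dm.consensus_differential(list(diff_tables.values()))
        tables["differential_consensus"] = consensus
        summary["differential"] = {
            name: int(t["significant"].sum()) for name, t in diff_tables.items()
        }
        summary["n_consensus_differential"] = int(len(consensus))
        _write(out_dir, "differential_consensus.tsv", consensus, manifest)
        log.info("differential consensus: %d probes", len(consensus))

        stage = "enrichment"
        background = filtered[0].probe_ids
        mqtl_cpgs = pd.Index(
            sorted({c for rec in validated_by_tissue.values()
                    for c in rec.loc[rec["hit"], "cpg_id"]})
        )
        summary["n_mqtl_cpgs"] = len(mqtl_cpgs)
        enrich = {}
        if len(mqtl_cpgs) and len(consensus_inf):
            res = ec.overlap_permutation_test(
                mqtl_cpgs, consensus_inf, background,
                n_perm=config.n_perm, seed=stage_seed(config.seed, "overlap"),
            )
            enrich["mqtl_vs_informative"] = res.as_dict()
        cm = filtered[0].cpg_manifest
        if cm is not None and len(mqtl_cpgs):
            for col in ("gene_region", "cgi_relation"):
                fe = ec.feature_enrichment(
                    mqtl_cpgs, cm, col, background,
                    n_perm=config.n_perm, fdr=config.fdr,
                    seed=stage_seed(config.seed, f"feature:{col}"),
                )
                _write(out_dir, f"enrichment_{col}.tsv", fe, manifest)
                enrich[col] = {
                    "n_significant": int(fe["significant"].sum()),
                    "fold_changes": fe["fold_change"].round(4).to_dict(),
                }
        summary["enrichment"] = enrich

        stage = "categorize"
        cats = ec.categorize(
            consensus_inf, consensus.index, mqtl_cpgs, background
        )
        tables["categories"] = cats
        summary["categories"] = ec.category_summary(cats).to_dict()
        _write(out_dir, "cpg_categories.tsv", cats, manifest)

        if truth is not None:
            stage = "truth_recovery"
            summary["recovery"] = _score_recovery(
                truth, consensus_inf, consensus, discovery_by_tissue,
                validated_by_tissue, background,
            )

        summary["manifest"] = manifest
        _write(out_dir, "summary.json", summary, manifest)
        if out_dir is not None:
            (out_dir / "FAILED").unlink(missing_ok=True)
            (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"summary": summary, "manifest": manifest, "tables": tables}
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc


def _subsample_differential_p(
    bundle: CohortBundle, sub_n: int, n_trials: int, seed: int
) -> pd.Series:
    """Trial-averaged paired signed-rank p-values on subsampled individuals."""
    from ._stats import paired_signed_rank

    rng = np.random.default_rng(seed)
    A = bundle.beta_a.values.to_numpy(dtype=float)
    B = bundle.beta_b.values.to_numpy(dtype=float)
    acc = np.zeros(A.shape[0])
    for _ in range(n_trials):
        idx = rng.choice(A.shape[1], size=sub_n, replace=False)
        _, p = paired_signed_rank(A[:, idx], B[:, idx])
        acc += p
    return pd.Series(acc / n_trials, index=bundle.probe_ids)


def _score_recovery(
    truth: TruthTable,
    consensus_inf: pd.Index,
    consensus_diff: pd.DataFrame,
    discovery_by_tissue: dict[str, pd.DataFrame],
    validated_by_tissue: dict[str, pd.DataFrame],
    background: pd.Index,
) -> dict[str, float]:
    """Compare pipeline calls with the planted truth (synthetic mode only)."""
    t = truth.cpgs.loc[truth.cpgs.index.intersection(background)]
    out: dict[str, float] = {}

    planted_inf = set(t.index[t["shared_variable"]])
    called_inf = set(consensus_inf)
    if planted_inf:
        out["informative_sensitivity"] = len(planted_inf & called_inf) / len(planted_inf)
    if called_inf:
        out["informative_precision"] = len(planted_inf & called_inf) / len(called_inf)

    planted_diff = set(t.index[t["differential"] & (t["delta"].abs() >= 0.05)])
    called_diff = set(consensus_diff.index)
    if planted_diff:
        out["differential_sensitivity"] = len(planted_diff & called_diff) / len(planted_diff)
    if called_diff:
        out["differential_precision"] = len(planted_diff & called_diff) / len(called_diff)

    tissue_key = {"BEC": "bec", "PBMC": "pbmc", "beta_a": "bec", "beta_b": "pbmc"}
    for tname, rec in discovery_by_tissue.items():
        key = tissue_key.get(tname, tname.lower())
        planted = truth.mqtl_pairs(key)
        if planted.empty or rec.empty:
            continue
        planted_pairs = set(map(tuple, planted[["snp_id", "cpg_id"]].to_numpy()))
        hits = set(map(tuple, rec.loc[rec["hit"], ["snp_id", "cpg_id"]].to_numpy()))
        out[f"mqtl_sensitivity_{key}"] = len(planted_pairs & hits) / len(planted_pairs)
        merged = rec.merge(planted, on=["snp_id", "cpg_id"])
        if len(merged):
            err = merged["effect_per_allele"] - merged[f"effect_{key}"]
            out[f"mqtl_effect_mae_{key}"] = float(err.abs().mean())
            out[f"mqtl_effect_bias_{key}"] = float(err.mean())
    # discovery vs validation effect agreement among validated pairs
    rhos = []
    for tname, vrec in validated_by_tissue.items():
        drec = discovery_by_tissue.get(tname)
        if drec is None or vrec.empty:
            continue
        m = vrec.loc[vrec["hit"]].merge(
            drec, on=["snp_id", "cpg_id"], suffixes=("_val", "_disc")
        )
        if len(m) >= 3:
            from scipy.stats import spearmanr

            rhos.append(spearmanr(m["effect_per_allele_disc"], m["effect_per_allele_val"])[0])
    if rhos:
        out["validation_effect_rho"] = float(np.mean(rhos))
    return out
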