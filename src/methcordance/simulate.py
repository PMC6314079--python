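"""Synthetic paired-tissue, paired-cohort methylation + genotype data.

Generates two (or more) cohorts of matched samples measured in a BEC-like
tissue (high inter-individual variability) and a PBMC-like tissue (lower
variability), with planted, recorded ground truth:

* bimodal baseline methylation across CpGs;
* individual-level variation on the logit scale, with a tissue-specific SD
  and shared across tissues at a configurable fraction of CpGs (the planted
  "informative" sites);
* additive cis genotype effects on the beta scale (tissue-specific or
  shared), each mQTL CpG linked to exactly one SNP placed < 5 kb away;
* tissue mean offsets (planted differential CpGs);
* cell-composition mixing (Dirichlet proportions over simulated pure cell
  profiles) and logit-scale measurement noise.

The truth of every planted feature is returned as a :class:`TruthTable` so
downstream stages can be scored for recovery. All randomness flows from a
single seed via named substreams; the same config yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_io import BetaMatrix, CohortBundle, CpGManifest, GenotypeMatrix, SNPManifest

__all__ = ["SimConfig", "TruthTable", "simulate_cohorts", "mix_cell_types"]

CIS_WINDOW = 5000  # bp; linked SNPs are placed strictly inside this window
_CPG_SPACING = 20_000  # bp between CpGs on a chromosome; keeps unlinked SNPs >= 5 kb away
_N_CHROM = 2


class ConfigError(ValueError):
    """A SimConfig field violates its invariant; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Defaults emulate the study design this package targets: two cohorts of
    79 and 16 children, each measured in both tissues, with the BEC-like
    tissue roughly twice as variable (logit SD 0.6 vs 0.3), about a third of
    CpGs differentially methylated between tissues, and per-allele genotype
    effects spanning the 3-15% beta range.
    """

    n_cpgs: int = 2000
    n_snps: int = 400
    cohort_sizes: Sequence[int] = (79, 16)
    frac_shared_variable: float = 0.15
    frac_mqtl_bec: float = 0.04
    frac_mqtl_pbmc: float = 0.04
    frac_mqtl_shared: float = 0.04
    effect_per_allele_range: tuple[float, float] = (0.03, 0.15)
    frac_differential: float = 0.35
    delta_range: tuple[float, float] = (0.05, 0.30)
    sd_indiv_bec: float = 0.6
    sd_indiv_pbmc: float = 0.3
    sd_noise: float = 0.08
    maf_range: tuple[float, float] = (0.05, 0.5)
    dirichlet_alpha: float = 5.0
    n_cell_types: int = 3
    frac_cell_specific: float = 0.2
    sd_cell_effect: float = 0.08
    frac_hwe_violation: float = 0.02
    frac_flag_sex: float = 0.0
    frac_poor_detection: float = 0.0
    missing_frac: float = 0.0
    seed: int = 0
    cohort_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        fracs = {
            "frac_shared_variable": self.frac_shared_variable,
            "frac_mqtl_bec": self.frac_mqtl_bec,
            "frac_mqtl_pbmc": self.frac_mqtl_pbmc,
            "frac_mqtl_shared": self.frac_mqtl_shared,
            "frac_differential": self.frac_differential,
            "frac_cell_specific": self.frac_cell_specific,
            "frac_hwe_violation": self.frac_hwe_violation,
            "frac_flag_sex": self.frac_flag_sex,
            "frac_poor_detection": self.frac_poor_detection,
            "missing_frac": self.missing_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.frac_mqtl_bec + self.frac_mqtl_pbmc + self.frac_mqtl_shared > 1.0:
            raise ConfigError("frac_mqtl_* must sum to at most 1")
        if self.n_cpgs < 1:
            raise ConfigError(f"n_cpgs must be positive, got {self.n_cpgs}")
        if any(n < 4 for n in self.cohort_sizes):
            raise ConfigError(f"cohort_sizes must all be >= 4, got {list(self.cohort_sizes)}")
        for name in ("effect_per_allele_range", "delta_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi < 1.0):
                raise ConfigError(f"{name} must be an interval within (0,1), got ({lo}, {hi})")
        for name in ("sd_indiv_bec", "sd_indiv_pbmc", "sd_noise"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must be within (0, 0.5], got ({lo}, {hi})")
        if self.n_cell_types < 2:
            raise ConfigError(f"n_cell_types must be >= 2, got {self.n_cell_types}")
        n_linked = self._n_linked
        if self.n_snps < n_linked:
            raise ConfigError(
                f"n_snps={self.n_snps} smaller than the {n_linked} SNPs needed for planted mQTL"
            )
        if self.n_snps - n_linked > self.n_cpgs:
            raise ConfigError("n_snps too large for the genomic layout (one unlinked SNP per CpG gap)")
        if not self.cohort_names:
            self.cohort_names = tuple(f"cohort{i + 1}" for i in range(len(self.cohort_sizes)))
        if len(self.cohort_names) != len(self.cohort_sizes):
            raise ConfigError("cohort_names length must match cohort_sizes")

    @property
    def _n_linked(self) -> int:
        return (
            int(round(self.frac_mqtl_bec * self.n_cpgs))
            + int(round(self.frac_mqtl_pbmc * self.n_cpgs))
            + int(round(self.frac_mqtl_shared * self.n_cpgs))
        )


@dataclass
class TruthTable:
    """Planted ground truth: one row per CpG and one per SNP.

    ``cpgs`` columns: baseline_bec, baseline_pbmc, delta (planted BEC-PBMC
    offset, 0 where not differential), differential, shared_variable,
    linked_snp ("" where none), effect_bec, effect_pbmc.
    ``snps`` columns: maf, hwe_violator.
    """

    cpgs: pd.DataFrame
    snps: pd.DataFrame

    def mqtl_pairs(self, tissue: str | None = None) -> pd.DataFrame:
        """Planted (snp_id, cpg_id, effect) rows; optionally only those with a
        nonzero effect in ``tissue`` ('bec' or 'pbmc')."""
        t = self.cpgs[self.cpgs["linked_snp"] != ""]
        out = pd.DataFrame(
            {
                "snp_id": t["linked_snp"],
                "cpg_id": t.index,
                "effect_bec": t["effect_bec"],
                "effect_pbmc": t["effect_pbmc"],
            }
        ).reset_index(drop=True)
        if tissue is not None:
            out = out[out[f"effect_{tissue}"] > 0].reset_index(drop=True)
        return out


def _draw_bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Mixture of mostly-unmethylated and mostly-methylated CpGs plus a
    minority of intermediate ones, echoing the bimodal beta distribution of
    methylation arrays."""
    comp = rng.choice(3, size=n, p=(0.42, 0.42, 0.16))
    lows = rng.beta(2.0, 12.0, size=n)
    highs = rng.beta(12.0, 2.0, size=n)
    mids = rng.uniform(0.2, 0.8, size=n)
    base = np.where(comp == 0, lows, np.where(comp == 1, highs, mids))
    return np.clip(base, 0.02, 0.98)


def _layout_genome(
    n_cpgs: int, n_linked: int, n_snps: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Place CpGs on 2 chromosomes with wide uniform spacing; linked SNPs at a
    random offset in [1, 4999] bp of their CpG, unlinked SNPs mid-gap so every
    unlinked pair is >= 5 kb apart or on another chromosome."""
    idx = np.arange(n_cpgs)
    chrom = np.array([f"chr{(i % _N_CHROM) + 1}" for i in idx])
    pos = 10_000 + (idx // _N_CHROM) * _CPG_SPACING
    cpg = pd.DataFrame({"chromosome": chrom, "position": pos})

    linked_cpg = rng.permutation(n_cpgs)[:n_linked]
    offsets = rng.integers(1, CIS_WINDOW, size=n_linked)
    signs = rng.choice((-1, 1), size=n_linked)
    linked_pos = pos[linked_cpg] + signs * offsets

    n_unlinked = n_snps - n_linked
    free = np.setdiff1d(idx, linked_cpg)
    host = rng.permutation(free)[:n_unlinked] if n_unlinked <= len(free) else np.concatenate(
        [rng.permutation(free), rng.permutation(linked_cpg)[: n_unlinked - len(free)]]
    )
    unlinked_pos = pos[host] + _CPG_SPACING // 2

    snp_chrom = np.concatenate([chrom[linked_cpg], chrom[host]])
    snp_pos = np.concatenate([linked_pos, unlinked_pos])
    snp = pd.DataFrame({"chromosome": snp_chrom, "position": snp_pos})
    return cpg, snp, linked_cpg


def simulate_cohorts(config: SimConfig) -> tuple[list[CohortBundle], TruthTable]:
    """Generate matched-tissue cohorts plus the planted truth.

    Truth (baselines, planted effects, MAFs, genomic layout) is shared across
    cohorts; individuals are drawn independently per cohort, so a discovery
    cohort and a validation cohort see the same underlying biology.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("truth", "genotypes", "samples", "cells", "noise", "qc"),
            ss.spawn(6),
        )
    }
    rng_truth = streams["truth"]
    n_cpgs, n_snps = config.n_cpgs, config.n_snps

    cpg_ids = pd.Index([f"cg{i:07d}" for i in range(n_cpgs)], name="probe_id")
    n_bec = int(round(config.frac_mqtl_bec * n_cpgs))
    n_pbmc = int(round(config.frac_mqtl_pbmc * n_cpgs))
    n_shared = int(round(config.frac_mqtl_shared * n_cpgs))
    n_linked = n_bec + n_pbmc + n_shared

    cpg_layout, snp_layout, linked_cpg = _layout_genome(n_cpgs, n_linked, n_snps, rng_truth)
    snp_ids = pd.Index([f"rs{i:07d}" for i in range(n_snps)], name="snp_id")

    baseline = _draw_bimodal_baseline(rng_truth, n_cpgs)
    # mQTL CpGs get mid-range baselines so additive allele effects stay on-scale
    baseline[linked_cpg] = rng_truth.uniform(0.2, 0.55, size=n_linked)

    effect_bec = np.zeros(n_cpgs)
    effect_pbmc = np.zeros(n_cpgs)
    effects = rng_truth.uniform(*config.effect_per_allele_range, size=n_linked)
    bec_cpgs = linked_cpg[:n_bec]
    pbmc_cpgs = linked_cpg[n_bec : n_bec + n_pbmc]
    shared_cpgs = linked_cpg[n_bec + n_pbmc :]
    effect_bec[bec_cpgs] = effects[:n_bec]
    effect_pbmc[pbmc_cpgs] = effects[n_bec : n_bec + n_pbmc]
    effect_bec[shared_cpgs] = effects[n_bec + n_pbmc :]
    effect_pbmc[shared_cpgs] = effects[n_bec + n_pbmc :]
    linked_snp = np.full(n_cpgs, "", dtype=object)
    linked_snp[linked_cpg] = snp_ids[: n_linked]

    shared_variable = np.zeros(n_cpgs, dtype=bool)
    shared_variable[rng_truth.permutation(n_cpgs)[: int(round(config.frac_shared_variable * n_cpgs))]] = True

    differential = np.zeros(n_cpgs, dtype=bool)
    differential[rng_truth.permutation(n_cpgs)[: int(round(config.frac_differential * n_cpgs))]] = True
    delta = np.zeros(n_cpgs)
    mag = rng_truth.uniform(*config.delta_range, size=int(differential.sum()))
    sign = rng_truth.choice((-1.0, 1.0), size=int(differential.sum()))
    delta[differential] = mag * sign

    base_bec = np.clip(baseline + delta / 2.0, 0.02, 0.98)
    base_pbmc = np.clip(baseline - delta / 2.0, 0.02, 0.98)

    maf = rng_truth.uniform(*config.maf_range, size=n_snps)
    hwe_violator = np.zeros(n_snps, dtype=bool)
    n_viol = int(round(config.frac_hwe_violation * n_snps))
    # only unlinked SNPs violate HWE so planted mQTL survive genotype QC
    unlinked = np.arange(n_linked, n_snps)
    if n_viol and len(unlinked):
        hwe_violator[rng_truth.permutation(unlinked)[:n_viol]] = True

    flag_sex = np.zeros(n_cpgs, dtype=bool)
    n_flag = int(round(config.frac_flag_sex * n_cpgs))
    if n_flag:
        # never flag planted CpGs: QC must not silently delete the truth
        unplanted = np.setdiff1d(np.arange(n_cpgs), linked_cpg)
        flag_sex[streams["qc"].permutation(unplanted)[:n_flag]] = True

    truth = TruthTable(
        cpgs=pd.DataFrame(
            {
                "baseline_bec": base_bec,
                "baseline_pbmc": base_pbmc,
                "delta": delta,
                "differential": differential,
                "shared_variable": shared_variable,
                "linked_snp": linked_snp,
                "effect_bec": effect_bec,
                "effect_pbmc": effect_pbmc,
            },
            index=cpg_ids,
        ),
        snps=pd.DataFrame({"maf": maf, "hwe_violator": hwe_violator}, index=snp_ids),
    )

    cell_offsets = np.zeros((config.n_cell_types, n_cpgs))
    n_cell_cpgs = int(round(config.frac_cell_specific * n_cpgs))
    cell_cpgs = streams["cells"].permutation(n_cpgs)[:n_cell_cpgs]
    cell_offsets[:, cell_cpgs] = streams["cells"].normal(
        0.0, config.sd_cell_effect, size=(config.n_cell_types, n_cell_cpgs)
    )

    cpg_manifest = CpGManifest(
        pd.DataFrame(
            {
                "chromosome": cpg_layout["chromosome"].to_numpy(),
                "position": cpg_layout["position"].to_numpy(),
                "gene_region": rng_truth.choice(
                    ("promoter", "intragenic", "intergenic"), size=n_cpgs, p=(0.3, 0.4, 0.3)
                ),
                "cgi_relation": rng_truth.choice(
                    ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea"),
                    size=n_cpgs,
                    p=(0.3, 0.1, 0.1, 0.05, 0.05, 0.4),
                ),
                "flag_sex": flag_sex,
                "flag_polymorphic": np.zeros(n_cpgs, dtype=bool),
                "flag_cross_hybridizing": np.zeros(n_cpgs, dtype=bool),
            },
            index=cpg_ids,
        )
    )
    snp_manifest = SNPManifest(
        pd.DataFrame(
            {
                "chromosome": snp_layout["chromosome"].to_numpy(),
                "position": snp_layout["position"].to_numpy(),
                "allele_a": np.full(n_snps, "A"),
                "allele_b": np.full(n_snps, "B"),
            },
            index=snp_ids,
        )
    )

    bundles = []
    for c, (n_ind, cname) in enumerate(zip(config.cohort_sizes, config.cohort_names)):
        rng_g = streams["genotypes"]
        rng_s = streams["samples"]
        rng_cell = streams["cells"]
        rng_noise = streams["noise"]
        sample_ids = pd.Index([f"{cname}_s{j:03d}" for j in range(n_ind)], name="sample_id")

        # genotypes at Hardy-Weinberg proportions; violators get forced excess hets
        p = maf[:, None]
        probs = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)[:, 0, :]
        u = rng_g.random((n_snps, n_ind))
        cum = probs.cumsum(axis=1)
        dosage = (u[:, :, None] > cum[:, None, :]).sum(axis=2).astype(float)
        viol_rows = np.flatnonzero(hwe_violator)
        if len(viol_rows):
            het = rng_g.random((len(viol_rows), n_ind)) < 0.9
            homo = rng_g.choice((0.0, 2.0), size=(len(viol_rows), n_ind))
            dosage[viol_rows] = np.where(het, 1.0, homo)

        # individual effects: one standard-normal draw per (cpg, individual),
        # shared across tissues at shared-variable CpGs
        z_shared = rng_s.normal(size=(n_cpgs, n_ind))
        z_bec = np.where(shared_variable[:, None], z_shared, rng_s.normal(size=(n_cpgs, n_ind)))
        z_pbmc = np.where(shared_variable[:, None], z_shared, rng_s.normal(size=(n_cpgs, n_ind)))

        props = rng_cell.dirichlet(
            np.full(config.n_cell_types, config.dirichlet_alpha), size=(2, n_ind)
        )

        tissues = {}
        for tname, base_t, z, sd, prop_t, eff in (
            ("bec", base_bec, z_bec, config.sd_indiv_bec, props[0], effect_bec),
            ("pbmc", base_pbmc, z_pbmc, config.sd_indiv_pbmc, props[1], effect_pbmc),
        ):
            signal = expit(logit(base_t)[:, None] + sd * z)
            eff_cpgs = np.flatnonzero(eff > 0)
            if len(eff_cpgs):
                snp_rows = [snp_ids.get_loc(s) for s in linked_snp[eff_cpgs]]
                signal[eff_cpgs] += eff[eff_cpgs, None] * dosage[snp_rows]
            signal = np.clip(signal, 0.0, 1.0)
            # cell mixing: pure profile per type = signal + type offset, then
            # per-sample proportion-weighted average
            pure = np.clip(signal[None, :, :] + cell_offsets[:, :, None], 0.0, 1.0)
            mixed = np.einsum("sk,kps->ps", prop_t, pure)
            noisy = expit(
                logit(np.clip(mixed, 1e-4, 1 - 1e-4))
                + rng_noise.normal(0.0, config.sd_noise, size=mixed.shape)
            )
            if config.missing_frac > 0:
                mask = rng_noise.random(noisy.shape) < config.missing_frac
                noisy = np.where(mask, np.nan, noisy)
            tissues[tname] = BetaMatrix(
                pd.DataFrame(noisy, index=cpg_ids, columns=sample_ids),
                tissue=tname.upper(),
                cohort=cname,
            )

        detection_p = None
        if config.frac_poor_detection > 0:
            det = np.abs(streams["qc"].normal(0.0, 0.002, size=(n_cpgs, n_ind)))
            bad = streams["qc"].permutation(n_cpgs)[: int(round(config.frac_poor_detection * n_cpgs))]
            det[bad] = streams["qc"].uniform(0.02, 0.5, size=(len(bad), n_ind))
            detection_p = pd.DataFrame(det, index=cpg_ids, columns=sample_ids)

        bundles.append(
            CohortBundle(
                name=cname,
                beta_a=tissues["bec"],
                beta_b=tissues["pbmc"],
                genotypes=GenotypeMatrix(pd.DataFrame(dosage, index=snp_ids, columns=sample_ids)),
                cpg_manifest=cpg_manifest,
                snp_manifest=snp_manifest,
                detection_p=detection_p,
            )
        )
    return bundles, truth


def mix_cell_types(
    pure_profiles: Mapping[str, pd.DataFrame] | Mapping[str, BetaMatrix],
    proportions: pd.DataFrame,
) -> BetaMatrix:
    """Proportion-weighted average of pure cell-type profiles.

    ``pure_profiles`` maps cell-type name -> (probes x samples) beta frame
    (or BetaMatrix); ``proportions`` is samples x cell types, each row a
    point on the simplex (nonnegative, summing to 1 within 1e-8).
    """
    frames = {
        k: (v.values if isinstance(v, BetaMatrix) else v) for k, v in pure_profiles.items()
    }
    names = list(frames)
    if set(proportions.columns) != set(names):
        raise ValueError("proportion columns must match pure-profile names")
    first = frames[names[0]]
    for k, f in frames.items():
        if not f.index.equals(first.index):
            raise ValueError(f"profile {k!r} does not share the CpG index")
    w = proportions.loc[:, names].to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("cell proportions must be nonnegative")
    if np.abs(w.sum(axis=1) - 1.0).max() > 1e-8:
        raise ValueError("cell proportions must sum to 1 per sample (tolerance 1e-8)")
    stack = np.stack([frames[k].to_numpy(dtype=float) for k in names])  # (k, p, s)
    mixed = np.einsum("sk,kps->ps", w, stack)
    return BetaMatrix(pd.DataFrame(mixed, index=first.index, columns=proportions.index))
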