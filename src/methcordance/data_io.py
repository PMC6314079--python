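"""Core data model, TSV input/output and probe quality-control filters.

All tabular formats are tab-separated UTF-8 with a header row; the first
column is the row identifier and ``NA`` marks missing values. Genomic
coordinates are 1-based inclusive throughout (matching array manifests);
BED export converts to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "GenotypeMatrix",
    "CpGManifest",
    "SNPManifest",
    "CohortBundle",
    "QCReport",
    "ParseError",
    "read_beta",
    "write_beta",
    "read_genotypes",
    "write_genotypes",
    "read_manifest",
    "write_manifest",
    "manifest_to_bed",
    "qc_filter_probes",
    "intersect_probes",
]

MISSING = "NA"

GENE_REGIONS = ("promoter", "intragenic", "intergenic", "enhancer", "3utr", "5utr")
CGI_RELATIONS = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")

#: genotype call strings accepted on input, mapped to allele-B dosage
_CALL_TO_DOSAGE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2, "0": 0, "1": 1, "2": 2}


class ParseError(ValueError):
    """Raised for malformed input tables; carries the offending row."""


@dataclass
class BetaMatrix:
    """CpGs x samples methylation fractions (beta values) for one tissue.

    Beta values express the methylated fraction at a CpG, from 0
    (unmethylated) to 1 (fully methylated). Missing entries are NaN.
    """

    values: pd.DataFrame  # probes x samples, float in [0, 1] or NaN
    tissue: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParseError("duplicate probe ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise ParseError("duplicate sample ids in beta matrix")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 0) | (arr > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"beta value out of [0,1] at probe {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        return replace(self, values=self.values.loc[list(probes)])

    def select_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return replace(self, values=self.values.loc[:, list(samples)])


@dataclass
class GenotypeMatrix:
    """SNPs x samples additive dosages (counts of the B allele, 0/1/2).

    Missing calls are NaN in ``dosage``; ``missing_mask`` exposes them as a
    boolean array of the same shape.
    """

    dosage: pd.DataFrame  # snps x samples, float in {0,1,2} or NaN

    def __post_init__(self) -> None:
        if self.dosage.index.has_duplicates:
            raise ParseError("duplicate SNP ids in genotype matrix")
        arr = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(arr) | np.isin(arr, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ParseError(
                f"dosage not in {{0,1,2,NA}} at SNP {self.dosage.index[i]!r}, "
                f"sample {self.dosage.columns[j]!r}"
            )

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage.to_numpy(dtype=float))

    def select_snps(self, snps: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[list(snps)])

    def select_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[:, list(samples)])


def _check_manifest(table: pd.DataFrame, required: Iterable[str], kind: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{kind} manifest missing columns: {missing}")
    if table.index.has_duplicates:
        raise ParseError(f"duplicate ids in {kind} manifest")
    if (table["position"] < 1).any():
        bad = table.index[table["position"] < 1][0]
        raise ParseError(f"{kind} manifest position < 1 at {bad!r}")


@dataclass
class CpGManifest:
    """Per-CpG coordinates and annotations used for cis-pairing and enrichment.

    Columns: chromosome, position (1-based), gene_region, cgi_relation, and
    the boolean QC flags flag_sex, flag_polymorphic, flag_cross_hybridizing.
    """

    table: pd.DataFrame

    REQUIRED = (
        "chromosome",
        "position",
        "gene_region",
        "cgi_relation",
        "flag_sex",
        "flag_polymorphic",
        "flag_cross_hybridizing",
    )

    def __post_init__(self) -> None:
        _check_manifest(self.table, self.REQUIRED, "CpG")
        for col, vocab in (("gene_region", GENE_REGIONS), ("cgi_relation", CGI_RELATIONS)):
            bad = set(self.table[col]) - set(vocab)
            if bad:
                raise ParseError(f"unknown {col} labels: {sorted(bad)}")

    @property
    def ids(self) -> pd.Index:
        return self.table.index

    def select(self, probes: Sequence[str]) -> "CpGManifest":
        return CpGManifest(self.table.loc[list(probes)])


@dataclass
class SNPManifest:
    """Per-SNP coordinates and alleles (columns: chromosome, position, allele_a, allele_b)."""

    table: pd.DataFrame

    REQUIRED = ("chromosome", "position", "allele_a", "allele_b")

    def __post_init__(self) -> None:
        _check_manifest(self.table, self.REQUIRED, "SNP")

    @property
    def ids(self) -> pd.Index:
        return self.table.index

    def select(self, snps: Sequence[str]) -> "SNPManifest":
        return SNPManifest(self.table.loc[list(snps)])


@dataclass
class CohortBundle:
    """One cohort's matched-tissue data: two beta matrices over identical
    samples, shared genotypes, manifests, and an optional detection-p matrix
    aligned to the beta matrices."""

    name: str
    beta_a: BetaMatrix  # e.g. BEC-like tissue
    beta_b: BetaMatrix  # e.g. PBMC-like tissue
    genotypes: GenotypeMatrix | None = None
    cpg_manifest: CpGManifest | None = None
    snp_manifest: SNPManifest | None = None
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        a, b = self.beta_a, self.beta_b
        if not a.probe_ids.equals(b.probe_ids):
            raise ValueError("tissue beta matrices must share the probe index")
        if not a.sample_ids.equals(b.sample_ids):
            shared = a.sample_ids.intersection(b.sample_ids)
            if shared.empty:
                raise ValueError("no shared sample ids between tissues")
            warnings.warn(
                f"dropping {len(a.sample_ids) + len(b.sample_ids) - 2 * len(shared)} "
                "unmatched samples across tissues",
                stacklevel=2,
            )
            self.beta_a = a.select_samples(shared)
            self.beta_b = b.select_samples(shared)
        if self.detection_p is not None:
            if not self.detection_p.index.equals(self.beta_a.probe_ids):
                raise ValueError("detection-p matrix not aligned to beta probes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta_a.probe_ids

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta_a.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_probes(self, probes: Sequence[str]) -> "CohortBundle":
        probes = list(probes)
        return CohortBundle(
            name=self.name,
            beta_a=self.beta_a.select_probes(probes),
            beta_b=self.beta_b.select_probes(probes),
            genotypes=self.genotypes,
            cpg_manifest=self.cpg_manifest.select(probes) if self.cpg_manifest else None,
            snp_manifest=self.snp_manifest,
            detection_p=self.detection_p.loc[probes] if self.detection_p is not None else None,
        )


@dataclass
class QCReport:
    """Counts of probes removed per rule, in application order."""

    n_input: int
    removed_flagged: int
    removed_detection_p: int
    removed_missingness: int
    n_output: int
    removed_ids: dict[str, list[str]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "removed_flagged": self.removed_flagged,
            "removed_detection_p": self.removed_detection_p,
            "removed_missingness": self.removed_missingness,
            "n_output": self.n_output,
        }


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        row = int(np.flatnonzero(df.index == dup)[-1]) + 2  # header is row 1
        raise ParseError(f"duplicate id {dup!r} at row {row} in {path}")
    df.index = df.index.astype(str)
    df.index.name = df.index.name or "id"
    return df


def read_beta(path: str | Path, tissue: str = "", cohort: str = "") -> BetaMatrix:
    df = _read_table(path)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric beta value in {path}: {exc}") from exc
    arr = values.to_numpy()
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if bad.any():
        i = int(np.argwhere(bad)[0][0])
        raise ParseError(f"beta out of [0,1] at row {i + 2} in {path}")
    return BetaMatrix(values, tissue=tissue, cohort=cohort)


def write_beta(beta: BetaMatrix, path: str | Path) -> None:
    beta.values.to_csv(path, sep="\t", na_rep=MISSING, float_format="%.12g")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a SNPs x samples dosage TSV; accepts 0/1/2 or AA/AB/BB calls."""
    df = _read_table(path)
    out = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for (i, j), cell in np.ndenumerate(raw):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            continue
        key = str(cell).strip()
        if key in ("", MISSING):
            continue
        try:
            out[i, j] = _CALL_TO_DOSAGE[key.upper() if key.isalpha() else str(int(float(key)))]
        except (KeyError, ValueError) as exc:
            raise ParseError(
                f"unknown dosage symbol {cell!r} at row {i + 2} in {path}"
            ) from exc
    return GenotypeMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    df = geno.dosage.copy()
    # integer display for calls, NA for missing
    out = df.map(lambda v: MISSING if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def read_manifest(path: str | Path, kind: str) -> CpGManifest | SNPManifest:
    """Read a CpG (``kind='cpg'``) or SNP (``kind='snp'``) manifest TSV."""
    df = _read_table(path)
    if kind == "cpg":
        for col in ("flag_sex", "flag_polymorphic", "flag_cross_hybridizing"):
            if col in df.columns:
                df[col] = df[col].astype(str).str.lower().isin(("true", "1", "yes"))
        df["position"] = df["position"].astype(int)
        return CpGManifest(df)
    if kind == "snp":
        df["position"] = df["position"].astype(int)
        return SNPManifest(df)
    raise ValueError(f"kind must be 'cpg' or 'snp', got {kind!r}")


def write_manifest(manifest: CpGManifest | SNPManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", na_rep=MISSING)


def manifest_to_bed(manifest: CpGManifest | SNPManifest, path: str | Path) -> None:
    """Export manifest coordinates as BED (0-based half-open, single-base features)."""
    t = manifest.table
    bed = pd.DataFrame(
        {
            "chrom": t["chromosome"],
            "start": t["position"] - 1,
            "end": t["position"],
            "name": t.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_vcf_genotypes(path: str | Path) -> tuple[GenotypeMatrix, SNPManifest]:
    """Minimal VCF ingest: GT field only, converted to alternate-allele dosage.

    Intended for small, uncompressed single-sample-block VCFs; anything
    requiring indexing or multi-allelic handling should be converted to the
    dosage TSV upstream.
    """
    rows, ids, chroms, poss, refs, alts = [], [], [], [], [], []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            dos = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) for a in gt.split("/"))))
            rows.append(dos)
            ids.append(vid)
            chroms.append(chrom)
            poss.append(pos)
            refs.append(ref)
            alts.append(alt)
    dosage = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    manifest = SNPManifest(
        pd.DataFrame(
            {"chromosome": chroms, "position": poss, "allele_a": refs, "allele_b": alts},
            index=pd.Index(ids, name="snp_id"),
        )
    )
    return GenotypeMatrix(dosage), manifest


# ---------------------------------------------------------------------------
# probe QC


def qc_filter_probes(
    bundle: CohortBundle,
    detection_p_threshold: float = 0.01,
    max_bad_sample_frac: float = 0.02,
    drop_flags: Iterable[str] = ("sex", "polymorphic", "cross_hybridizing"),
) -> tuple[CohortBundle, QCReport]:
    """Remove low-quality probes from a cohort bundle.

    Rules are applied in a fixed order so report counts are deterministic:

    1. manifest flags (sex-chromosome, polymorphic-target, cross-hybridizing);
    2. detection p-value above ``detection_p_threshold`` in more than
       ``max_bad_sample_frac`` of samples;
    3. missing beta values in more than ``max_bad_sample_frac`` of samples.

    A probe failing a rule in either tissue is removed from both. Each probe
    is counted once, under the first rule it fails.
    """
    probes = bundle.probe_ids
    n_input = len(probes)
    removed: dict[str, list[str]] = {"flagged": [], "detection_p": [], "missingness": []}
    alive = pd.Series(True, index=probes)

    if bundle.cpg_manifest is not None and drop_flags:
        flags = bundle.cpg_manifest.table.loc[probes]
        flagged = pd.Series(False, index=probes)
        for f in drop_flags:
            flagged |= flags[f"flag_{f}"].astype(bool)
        removed["flagged"] = list(probes[flagged])
        alive &= ~flagged

    if bundle.detection_p is not None:
        det = bundle.detection_p.loc[probes].to_numpy(dtype=float)
        frac_bad = (det > detection_p_threshold).mean(axis=1)
        fail = pd.Series(frac_bad > max_bad_sample_frac, index=probes)
        removed["detection_p"] = list(probes[alive & fail])
        alive &= ~fail

    for beta in (bundle.beta_a, bundle.beta_b):
        frac_na = beta.values.isna().mean(axis=1)
        fail = frac_na > max_bad_sample_frac
        removed["missingness"].extend(probes[alive & fail])
        alive &= ~fail
    removed["missingness"] = sorted(set(removed["missingness"]), key=list(probes).index)

    surviving = list(probes[alive])
    if not surviving:
        warnings.warn("probe QC removed every probe", stacklevel=2)
    report = QCReport(
        n_input=n_input,
        removed_flagged=len(removed["flagged"]),
        removed_detection_p=len(removed["detection_p"]),
        removed_missingness=len(removed["missingness"]),
        n_output=len(surviving),
        removed_ids=removed,
    )
    return bundle.select_probes(surviving), report


def intersect_probes(bundles: Sequence[CohortBundle]) -> list[CohortBundle]:
    """Restrict all bundles to their common probe ids, in the first bundle's order."""
    if len(bundles) < 2:
        raise ValueError("need at least two bundles to intersect")
    common = set(bundles[0].probe_ids)
    for b in bundles[1:]:
        common &= set(b.probe_ids)
    if not common:
        raise ValueError("empty probe intersection across bundles")
    ordered = [p for p in bundles[0].probe_ids if p in common]
    return [b.select_probes(ordered) for b in bundles]
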