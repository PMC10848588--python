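"""Genotype containers, file formats, quality control, and marker subsampling.

The central container is :class:`GenotypeMatrix`: individuals x markers
integer codes in {0, 1, 2, MISSING} counting copies of a declared allele,
plus a marker map (chromosome, bp, allele pair).  Readers/writers cover
PLINK 1 bed/bim/fam triples and VCF 4.x (GT field), and round-trip the
matrix bit-exactly including missingness.

QC applies the standard marker filters in a fixed order (autosome,
call rate, minor allele frequency, Hardy-Weinberg equilibrium) so the
report attributes each dropped marker to exactly one reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 2-bit codes (per genotype, little-endian within byte):
#   00 = hom A1 (2 copies of counted allele), 01 = missing, 10 = het, 11 = hom A2
_CODE_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_BITS_TO_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-count codes with a marker map.

    Parameters
    ----------
    codes
        ``(n, m)`` int8 array with entries in ``{0, 1, 2, MISSING}``; each
        entry counts copies of the marker's counted allele (``a1``).
    individual_ids
        Length-``n`` sequence of unique ids.
    marker_map
        DataFrame with columns ``chrom``, ``pos``, ``a1`` (counted allele),
        ``a2``; bp positions strictly increasing within each chromosome.
    haplotypes
        Optional ``(n, 2, m)`` phased 0/1 array (carried by the simulator so
        gene dropping can transmit real haplotypes); not persisted to disk.
    """

    codes: np.ndarray
    individual_ids: np.ndarray
    marker_map: pd.DataFrame
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x markers)")
        n, m = self.codes.shape
        if len(self.individual_ids) != n:
            raise ValueError(
                f"{len(self.individual_ids)} ids for {n} rows of codes"
            )
        if len(self.marker_map) != m:
            raise ValueError(f"marker_map has {len(self.marker_map)} rows for {m} markers")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes restricted to {0,1,2,MISSING}")
        mm = self.marker_map
        for chrom, grp in mm.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Observed frequency of the counted allele, on non-missing calls."""
        obs = self.codes != MISSING
        n_called = obs.sum(axis=0)
        totals = np.where(obs, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = totals / (2.0 * n_called)
        return np.where(n_called > 0, p, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=0)

    def dosage(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Float codes with missing entries mean-imputed to 2p.

        Imputation happens only here, at matrix-construction time; the stored
        codes keep their missingness.
        """
        x = self.codes.astype(np.float64)
        p = self.allele_frequency() if freqs is None else np.asarray(freqs, float)
        miss = self.codes == MISSING
        if miss.any():
            fill = np.broadcast_to(2.0 * np.nan_to_num(p), x.shape)
            x[miss] = fill[miss]
        return x

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        idx = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            rows = np.array([idx[i] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"id {e.args[0]!r} not in genotype matrix") from None
        hap = self.haplotypes[rows] if self.haplotypes is not None else None
        return GenotypeMatrix(
            self.codes[rows], np.asarray(list(ids), dtype=object),
            self.marker_map.reset_index(drop=True), hap,
        )

    def subset_markers(self, cols: np.ndarray) -> "GenotypeMatrix":
        cols = np.asarray(cols, dtype=int)
        hap = self.haplotypes[:, :, cols] if self.haplotypes is not None else None
        return GenotypeMatrix(
            self.codes[:, cols], self.individual_ids,
            self.marker_map.iloc[cols].reset_index(drop=True), hap,
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """Write a PLINK 1 bed/bim/fam triple (SNP-major bed, v1.00 magic)."""
    n, m = g.codes.shape
    bim = pd.DataFrame(
        {
            "chrom": g.marker_map["chrom"],
            "snp": [f"{c}_{p}" for c, p in zip(g.marker_map["chrom"], g.marker_map["pos"])],
            "cm": 0,
            "pos": g.marker_map["pos"],
            "a1": g.marker_map["a1"],
            "a2": g.marker_map["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.individual_ids,
            "iid": g.individual_ids,
            "sire": "0",
            "dam": "0",
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep=" ", header=False, index=False)

    # pack codes 4-per-byte, SNP-major: one row of bytes per marker
    bits = np.empty((m, n), dtype=np.uint8)
    for code, b in _CODE_TO_BITS.items():
        bits[g.codes.T == code] = b
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = bits
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def _read_plink(prefix: str) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix + ".bim", sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix + ".fam", sep=r"\s+", header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"], dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes {magic!r} (expected PLINK v1.00 SNP-major)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if raw.size != m * n_bytes:
        raise ValueError(
            f"{prefix}.bed: {raw.size} data bytes but bim/fam imply {m} x {n_bytes}"
        )
    raw = raw.reshape(m, n_bytes)
    two_bit = np.empty((m, n_bytes * 4), dtype=np.uint8)
    two_bit[:, 0::4] = raw & 0b11
    two_bit[:, 1::4] = (raw >> 2) & 0b11
    two_bit[:, 2::4] = (raw >> 4) & 0b11
    two_bit[:, 3::4] = (raw >> 6) & 0b11
    codes = _BITS_TO_CODE[two_bit[:, :n]].T
    marker_map = pd.DataFrame(
        {"chrom": bim["chrom"], "pos": bim["pos"], "a1": bim["a1"], "a2": bim["a2"]}
    )
    return GenotypeMatrix(codes, fam["iid"].to_numpy(dtype=object), marker_map)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write genotypes as a minimal VCF 4.2 file (GT field only).

    ``a2`` is written as REF and the counted allele ``a1`` as ALT, so the
    code (ALT-allele count) round-trips through standard VCF semantics.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.marker_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in g.individual_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        mm = g.marker_map
        for j in range(g.n_markers):
            fields = [
                str(mm["chrom"].iat[j]), str(mm["pos"].iat[j]), f"snp{j}",
                str(mm["a2"].iat[j]), str(mm["a1"].iat[j]), ".", ".", ".", "GT",
            ]
            fields += [gt_str[int(c)] for c in g.codes[:, j]]
            fh.write("\t".join(fields) + "\n")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    ids = np.asarray(vcf.samples, dtype=object)
    codes_cols, chroms, poss, a1s, a2s = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # gts012: 0/1/2 ALT copies, 3=missing
        gt[gt == 3] = MISSING
        codes_cols.append(gt)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        a1s.append(v.ALT[0])
        a2s.append(v.REF)
    vcf.close()
    if n_skipped:
        log.info("skipped %d non-biallelic VCF records", n_skipped)
    if not codes_cols:
        raise ValueError(f"{path}: no biallelic records")
    codes = np.column_stack(codes_cols)
    marker_map = pd.DataFrame({"chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s})
    return GenotypeMatrix(codes, ids, marker_map)


def read_genotypes(path: str, format: str = "plink_bed") -> GenotypeMatrix:
    """Read genotypes from a PLINK bed/bim/fam prefix or a VCF file."""
    if format == "plink_bed":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}; use 'plink_bed' or 'vcf'")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test by full enumeration.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one (the standard exact-test convention in GWAS QC).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("zero total genotype count")
    n_a = 2 * n_aa + n_Aa  # minor-allele count (label-symmetric below)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def logprob(h):
        hom_rare = (rare - h) // 2
        hom_common = (2 * n - rare - h) // 2
        return (
            gammaln(n + 1)
            - gammaln(h + 1) - gammaln(hom_rare + 1) - gammaln(hom_common + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )

    lp = logprob(hets.astype(float))
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    obs = probs[hets == n_Aa][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    """Per-filter accounting of one :func:`qc_filter` pass.

    Each dropped marker is attributed to the first failing filter in the
    fixed order (non_autosome, call_rate, maf, hwe), so the removal counts
    partition the dropped set.
    """

    n_markers_in: int
    n_markers_out: int
    removals: dict
    per_marker: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.per_marker

    def write(self, path: str) -> None:
        self.per_marker.to_csv(path, sep="\t", index=False)


_AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M", "Z", "W", "23", "24", "25", "26"}


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-6,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the marker QC filters in the fixed order autosome, call rate, MAF, HWE.

    MAF is computed on non-missing calls only. A threshold of 0 (or
    ``hwe_p_min=0`` / ``autosomes_only=False``) disables that filter.
    Raises if nothing survives, naming the filter that removed most markers.
    """
    m = g.n_markers
    chrom = g.marker_map["chrom"].astype(str).str.upper().to_numpy()
    call = g.call_rate()
    maf = g.maf()
    reason = np.full(m, "", dtype=object)

    if autosomes_only:
        bad = np.isin(chrom, list(_AUTOSOME_EXCLUDE))
        reason[(reason == "") & bad] = "non_autosome"
    bad = call < call_rate_min
    reason[(reason == "") & bad] = "call_rate"
    bad = ~(maf >= maf_min)  # NaN MAF (all-missing) caught by call_rate first
    if maf_min > 0:
        reason[(reason == "") & bad] = "maf"

    hwe_p = np.ones(m)
    if hwe_p_min > 0:
        for j in np.flatnonzero(reason == ""):
            col = g.codes[:, j]
            counts = (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
            if sum(counts) > 0:
                hwe_p[j] = hwe_test(*counts)
        reason[(reason == "") & (hwe_p < hwe_p_min)] = "hwe"

    keep = np.flatnonzero(reason == "")
    removals = {
        k: int((reason == k).sum()) for k in ("non_autosome", "call_rate", "maf", "hwe")
    }
    report = QCReport(
        n_markers_in=m,
        n_markers_out=len(keep),
        removals=removals,
        per_marker=pd.DataFrame(
            {
                "chrom": g.marker_map["chrom"],
                "pos": g.marker_map["pos"],
                "maf": maf,
                "call_rate": call,
                "hwe_p": hwe_p,
                "removed_by": reason,
            }
        ),
    )
    if len(keep) == 0:
        worst = max(removals, key=removals.get)
        raise ValueError(f"all {m} markers removed by QC (dominating filter: {worst})")
    return g.subset_markers(keep), report


def subsample_markers(g: GenotypeMatrix, target_count: int, seed: int) -> GenotypeMatrix:
    """Uniform random marker subset without replacement, map order preserved."""
    if target_count > g.n_markers:
        raise ValueError(f"target_count {target_count} exceeds available {g.n_markers}")
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    rng = np.random.default_rng(seed)
    cols = np.sort(rng.choice(g.n_markers, size=target_count, replace=False))
    return g.subset_markers(cols)


# ---------------------------------------------------------------------------
# Delimited pedigree and phenotype files


def write_pedigree(ped, path: str) -> None:
    """Write 3-column delimited pedigree (id, sire, dam; 0 = unknown)."""
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\n")
        for i, s, d in ped.records:
            fh.write(f"{i}\t{s or '0'}\t{d or '0'}\n")


def read_pedigree(path: str):
    from .simdata import Pedigree, UNKNOWN

    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    recs = [
        (r.iloc[0], UNKNOWN if r.iloc[1] == "0" else r.iloc[1],
         UNKNOWN if r.iloc[2] == "0" else r.iloc[2])
        for _, r in df.iterrows()
    ]
    return Pedigree(recs)


def write_phenotypes(pheno, path: str) -> None:
    pheno.df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str, trait_cols=None, factor_cols=("sex", "feed_room")):
    from .simdata import PhenotypeTable

    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    if trait_cols is None:
        trait_cols = [c for c in df.columns if c not in ("id",) + tuple(factor_cols)]
    return PhenotypeTable(df, trait_cols=list(trait_cols), factor_cols=list(factor_cols))
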