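"""Consensus somatic call sets, twin shared/unique partition, and SV merging.

The high-confidence small-variant call set for each twin is the exact
intersection of three somatic callers' PASS calls (with the 'somatic' INFO
flag where the caller emits one). Variants are then classified as shared
between the twins or unique to one, and filtered on germline/tumor VAF,
depth and mutation multiplicity. Structural variants are merged across two
callers with a +/-200 bp breakpoint slop, a CNV-changepoint rescue route,
and a hard veto on any alt evidence in the matched normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

VariantKey = tuple[str, int, str, str]

#: filter defaults, as used throughout the pipeline
GERMLINE_VAF_MAX = 0.05
TUMOR_VAF_MIN = 0.10
MIN_DEPTH = 20
SV_SLOP_BP = 200


@dataclass(frozen=True)
class SomaticVariant:
    """One small somatic variant with per-caller status and read counts."""

    chrom: str
    pos: int  # 1-based (VCF)
    ref: str
    alt: str
    tumor_alt: int = 0
    tumor_depth: int = 0
    germline_alt: int = 0
    germline_depth: int = 0
    caller_flags: tuple[bool, ...] = ()
    multiplicity: int | None = None

    def __post_init__(self) -> None:
        if self.tumor_alt > self.tumor_depth or self.germline_alt > self.germline_depth:
            raise ValueError(f"alt reads exceed depth at {self.chrom}:{self.pos}")

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def germline_vaf(self) -> float:
        return self.germline_alt / self.germline_depth if self.germline_depth else 0.0

    def key(self, normalized: bool = True) -> VariantKey:
        if normalized:
            pos, ref, alt = normalize_allele(self.pos, self.ref, self.alt)
            return (self.chrom, pos, ref, alt)
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CallSetPartition:
    """Twin call sets split into shared and twin-unique lists."""

    shared: list[SomaticVariant]
    unique_a: list[SomaticVariant]
    unique_b: list[SomaticVariant]
    match_key: str = "normalized"
    #: for shared variants, twin B's copy of the record (same key)
    shared_b: list[SomaticVariant] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lineage, pool in (
            ("shared", self.shared), ("unique_a", self.unique_a), ("unique_b", self.unique_b)
        ):
            for v in pool:
                rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                             "alt": v.alt, "vtype": v.vtype, "lineage": lineage,
                             "tumor_alt": v.tumor_alt, "tumor_depth": v.tumor_depth})
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "vtype", "lineage",
                           "tumor_alt", "tumor_depth"])


@dataclass(frozen=True)
class SvCall:
    """A structural-variant call as a breakpoint pair."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    caller: str
    normal_alt_evidence: int = 0

    def __post_init__(self) -> None:
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            raise ValueError("pos1 must be <= pos2 on the same chromosome")


def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: trim the shared suffix, then the shared prefix.

    This is parsimony-style normalization without reference context (no left
    shifting through repeats); enough to reconcile caller padding conventions.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

CALLER_DIALECTS = {
    "mutect2": "strict_pass",
    "strelka2": "pass_and_somatic",
    "octopus": "pass_and_somatic",
}


def read_caller_vcf(
    path: str | Path,
    caller_dialect: str = "pass_and_somatic",
    tumor_sample: str | int = 0,
    normal_sample: str | int = 1,
) -> list[SomaticVariant]:
    """Read one caller's somatic VCF, keeping records per the dialect's rule.

    ``strict_pass`` keeps FILTER==PASS records; ``pass_and_somatic``
    additionally requires the SOMATIC INFO flag. Multi-allelic records are
    split into one bi-allelic variant per ALT allele. Tumor/germline allele
    counts are taken from AD (falling back to DP for depth).
    """
    from cyvcf2 import VCF

    if caller_dialect not in ("strict_pass", "pass_and_somatic"):
        raise ValueError(f"unknown caller dialect: {caller_dialect!r}")
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    t_idx = samples.index(tumor_sample) if isinstance(tumor_sample, str) else tumor_sample
    n_idx = samples.index(normal_sample) if isinstance(normal_sample, str) else normal_sample

    out: list[SomaticVariant] = []
    for rec in vcf:
        # cyvcf2 FILTER is None for PASS/'.'; treat only explicit PASS or missing as pass
        if rec.FILTER is not None:
            continue
        if caller_dialect == "pass_and_somatic" and rec.INFO.get("SOMATIC") is None:
            continue
        ad = rec.format("AD")
        dp = rec.format("DP")
        for ai, alt in enumerate(rec.ALT):
            if alt is None or alt in (".", "*"):
                continue
            t_alt, t_dep = _counts(ad, dp, t_idx, ai)
            n_alt, n_dep = _counts(ad, dp, n_idx, ai) if n_idx is not None else (0, 0)
            out.append(
                SomaticVariant(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    tumor_alt=t_alt, tumor_depth=t_dep,
                    germline_alt=n_alt, germline_depth=n_dep,
                )
            )
    return out


def _counts(ad, dp, sample_idx: int, alt_idx: int) -> tuple[int, int]:
    if ad is not None:
        row = ad[sample_idx]
        alt_reads = max(0, int(row[alt_idx + 1]))
        depth = int(sum(max(0, int(x)) for x in row))
        return alt_reads, depth
    if dp is not None:
        return 0, max(0, int(dp[sample_idx][0]))
    return 0, 0


# ---------------------------------------------------------------------------
# intersection and partition
# ---------------------------------------------------------------------------

def intersect_callers(
    *callsets: list[SomaticVariant], normalized: bool = True
) -> list[SomaticVariant]:
    """Variants present in every caller's list (exact key match).

    Read counts on the output are taken from the first call set; caller
    flags are all true by construction. Order-invariant and idempotent.
    """
    if not callsets:
        return []
    keyed = [{v.key(normalized): v for v in cs} for cs in callsets]
    common = set(keyed[0])
    for k in keyed[1:]:
        common &= set(k)
    out = []
    for key in common:
        v = keyed[0][key]
        out.append(replace(v, caller_flags=tuple([True] * len(callsets))))
    out.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return out


def classify_shared_unique(
    set_a: list[SomaticVariant],
    set_b: list[SomaticVariant],
    normalized: bool = True,
) -> CallSetPartition:
    """Split two twins' high-confidence sets into shared / unique lists."""
    keys_a = {v.key(normalized): v for v in set_a}
    keys_b = {v.key(normalized): v for v in set_b}
    shared_keys = set(keys_a) & set(keys_b)
    order = lambda v: (v.chrom, v.pos, v.ref, v.alt)
    return CallSetPartition(
        shared=sorted((keys_a[k] for k in shared_keys), key=order),
        shared_b=sorted((keys_b[k] for k in shared_keys), key=order),
        unique_a=sorted((v for k, v in keys_a.items() if k not in shared_keys), key=order),
        unique_b=sorted((v for k, v in keys_b.items() if k not in shared_keys), key=order),
        match_key="normalized" if normalized else "literal",
    )


# ---------------------------------------------------------------------------
# VAF / depth / multiplicity filters
# ---------------------------------------------------------------------------

def filter_vaf_depth(
    variants: list[SomaticVariant],
    germline_vaf_max: float = GERMLINE_VAF_MAX,
    tumor_vaf_min: float = TUMOR_VAF_MIN,
    min_depth: int = MIN_DEPTH,
    require_multiplicity: bool = True,
) -> tuple[list[SomaticVariant], pd.DataFrame]:
    """Apply the study's per-variant quality filters.

    A variant is removed when germline VAF > ``germline_vaf_max``, tumor VAF
    < ``tumor_vaf_min``, total tumor coverage < ``min_depth``, or (when
    required) its multiplicity estimate is zero. Thresholds are strict
    inequalities, so VAF exactly 0.10 at depth exactly 20 survives. Returns
    the survivors plus a removal log recording the first rule that fired.
    """
    kept: list[SomaticVariant] = []
    log_rows = []
    for v in variants:
        reason = None
        if v.tumor_depth == 0:
            reason = "no coverage"
        elif v.germline_vaf > germline_vaf_max:
            reason = "germline VAF"
        elif v.tumor_vaf < tumor_vaf_min:
            reason = "tumor VAF"
        elif v.tumor_depth < min_depth:
            reason = "depth"
        elif require_multiplicity and (v.multiplicity is not None and v.multiplicity == 0):
            reason = "multiplicity zero"
        if reason is None:
            kept.append(v)
        else:
            log_rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                             "alt": v.alt, "reason": reason,
                             "tumor_vaf": round(v.tumor_vaf, 4),
                             "germline_vaf": round(v.germline_vaf, 4),
                             "tumor_depth": v.tumor_depth})
    log = pd.DataFrame(log_rows, columns=["chrom", "pos", "ref", "alt", "reason",
                                          "tumor_vaf", "germline_vaf", "tumor_depth"])
    return kept, log


# ---------------------------------------------------------------------------
# structural variants
# ---------------------------------------------------------------------------

def _breakpoints_match(a: SvCall, b: SvCall, slop_bp: int) -> bool:
    return (
        a.svtype == b.svtype
        and a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) <= slop_bp
        and abs(a.pos2 - b.pos2) <= slop_bp
    )


def _near_changepoint(sv: SvCall, changepoints: list[tuple[str, int]], slop_bp: int) -> bool:
    for chrom, pos in changepoints:
        if (sv.chrom1 == chrom and abs(sv.pos1 - pos) <= slop_bp) or (
            sv.chrom2 == chrom and abs(sv.pos2 - pos) <= slop_bp
        ):
            return True
    return False


def merge_sv_calls(
    caller1_svs: list[SvCall],
    caller2_svs: list[SvCall],
    cnv_changepoints: list[tuple[str, int]] | None = None,
    slop_bp: int = SV_SLOP_BP,
) -> list[SvCall]:
    """Two-route SV consensus.

    An SV survives if (a) both callers report it with both breakpoints within
    ``slop_bp``, or (b) one caller reports it and a CNV changepoint lies
    within ``slop_bp`` of either breakpoint. Calls with any alt evidence in
    the matched normal are removed before matching. Matching calls are merged
    transitively (union-find over pairwise matches); each merged group is
    represented by its first caller-1 member (else caller-2).
    """
    cnv_changepoints = cnv_changepoints or []
    calls = [sv for sv in caller1_svs + caller2_svs if sv.normal_alt_evidence == 0]
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _breakpoints_match(calls[i], calls[j], slop_bp):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[SvCall]] = {}
    for i, sv in enumerate(calls):
        groups.setdefault(find(i), []).append(sv)

    out = []
    for members in groups.values():
        callers = {sv.caller for sv in members}
        supported = len(callers) >= 2 or any(
            _near_changepoint(sv, cnv_changepoints, slop_bp) for sv in members
        )
        if supported:
            rep = next((sv for sv in members if sv in caller1_svs), members[0])
            out.append(rep)
    out.sort(key=lambda sv: (sv.chrom1, sv.pos1, sv.chrom2, sv.pos2))
    return out


def read_changepoints_bed(path: str | Path) -> list[tuple[str, int]]:
    """BED (0-based half-open) changepoints -> 1-based positions."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return [(str(r.chrom), int(r.start) + 1) for r in df.itertuples()]


def read_svs_bedpe(path: str | Path, caller: str) -> list[SvCall]:
    """BEDPE SV calls (0-based starts) -> SvCall list (1-based breakpoints)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        svtype = str(row[6]) if len(row) > 6 else "BND"
        ao = int(row[7]) if len(row) > 7 else 0
        out.append(SvCall(chrom1=str(row[0]), pos1=int(row[1]) + 1,
                          chrom2=str(row[3]), pos2=int(row[4]) + 1,
                          svtype=svtype, caller=caller, normal_alt_evidence=ao))
    return out
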