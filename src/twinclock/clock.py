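"""Clock-like N[C>T]pG mutation identification and lineage count assembly.

C>T substitutions at CpG sites (any 5' base, reference G at the 3' neighbor:
N[C>T]pG) arise predominantly by spontaneous deamination of 5-methylcytosine
and accrue at a near-constant rate, making them a molecular clock for timing
clonal ancestors. This module classifies consensus variants against the
reference trinucleotide context (strand-normalizing G>A calls), assembles
the count triple (shared s, unique-A n_A, unique-B n_B) that the timing
model consumes, and computes genome-wide burden summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

GENOME_MB = 3100.0


@dataclass
class LineageCounts:
    """Sufficient statistics for the MRCA timing model."""

    s_shared: int
    n_unique_a: int
    n_unique_b: int
    context_class: str = "all_clonal"  # or 'ncptg'
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.s_shared, self.n_unique_a, self.n_unique_b) < 0:
            raise ValueError("lineage counts must be non-negative")

    def as_dict(self) -> dict:
        return {"s": self.s_shared, "n_a": self.n_unique_a, "n_b": self.n_unique_b,
                "context_class": self.context_class, "filters": self.provenance}


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_ncptg(chrom: str, pos: int, ref: str, alt: str, reference) -> bool:
    """True iff the variant is an N[C>T]pG clock mutation.

    ``reference`` is a mapping chrom -> sequence (e.g. a ``pyfaidx.Fasta``).
    On the pyrimidine strand the call must be C>T with a reference G
    immediately 3'; a G>A call is evaluated on the reverse complement
    (true iff the reference base immediately 5' is C). Indels and other
    substitutions are never clock mutations. Variants at a contig edge
    (missing neighbor) return False.
    """
    if len(ref) != 1 or len(alt) != 1:
        return False
    seq = reference[chrom]
    i = pos - 1  # FASTA is 0-based
    ref_base = str(seq[i]).upper()
    if ref_base != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref}, found {ref_base}")
    if ref == "C" and alt == "T":
        if i + 1 >= len(seq):
            return False
        return str(seq[i + 1]).upper() == "G"
    if ref == "G" and alt == "A":
        if i == 0:
            return False
        return str(seq[i - 1]).upper() == "C"
    return False


def classify_ncptg_from_context(context: str, ref: str, alt: str) -> bool:
    """Classify from a pre-extracted reference 3-mer centred on the site."""
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        return False
    context = context.upper()
    if ref == "C" and alt == "T":
        return context[2] == "G"
    if ref == "G" and alt == "A":
        return context[0] == "C"
    return False


# ---------------------------------------------------------------------------
# lineage count assembly
# ---------------------------------------------------------------------------

def assemble_lineage_counts(
    partition: pd.DataFrame,
    lineage_labels: pd.DataFrame | None = None,
    context_filter: str = "all_clonal",
    reference=None,
    min_depth: int = 20,
) -> LineageCounts:
    """Build the (s, n_A, n_B) triple consumed by the timing model.

    ``partition`` needs columns chrom, pos, ref, alt, lineage
    (shared/unique_a/unique_b) and optionally cluster, depth_a, depth_b,
    multiplicity, context. ``lineage_labels`` (cluster -> label from the
    pigeonhole assignment) restricts counting to the MPN lineage: shared
    variants in ``ancestral`` clusters feed s, twin-unique variants in their
    twin's ``lineage_*`` (or ancestral) clusters feed n_i. Without labels,
    every partition member counts (the labels are then assumed upstream).
    ``context_filter='ncptg'`` additionally keeps only clock mutations,
    classified from ``reference`` or a ``context`` column. Depth and
    multiplicity filters apply when those columns are present.
    """
    if context_filter not in ("all_clonal", "ncptg"):
        raise ValueError(f"unknown context filter: {context_filter!r}")
    df = partition.copy()
    trail: list[str] = [f"input n={len(df)}"]

    if "depth_a" in df.columns and "depth_b" in df.columns:
        before = len(df)
        shared = df["lineage"] == "shared"
        ok = np.where(
            shared,
            (df["depth_a"] >= min_depth) & (df["depth_b"] >= min_depth),
            np.where(df["lineage"] == "unique_a",
                     df["depth_a"] >= min_depth, df["depth_b"] >= min_depth),
        )
        df = df[ok]
        trail.append(f"depth>={min_depth}: removed {before - len(df)}")
    if "multiplicity" in df.columns:
        before = len(df)
        df = df[df["multiplicity"] > 0]
        trail.append(f"multiplicity>0: removed {before - len(df)}")

    if lineage_labels is not None:
        if "cluster" not in df.columns:
            raise ValueError("partition lacks a 'cluster' column for lineage labels")
        label_of = dict(zip(lineage_labels["cluster"], lineage_labels["label"]))
        missing = set(df["cluster"]) - set(label_of)
        if missing:
            raise ValueError(f"no lineage label for clusters {sorted(missing)}")
        lab = df["cluster"].map(label_of)
        before = len(df)
        on_lineage = (
            ((df["lineage"] == "shared") & (lab == "ancestral"))
            | ((df["lineage"] == "unique_a") & lab.isin(["lineage_a", "ancestral"]))
            | ((df["lineage"] == "unique_b") & lab.isin(["lineage_b", "ancestral"]))
        )
        df = df[on_lineage]
        trail.append(f"lineage restriction: removed {before - len(df)}")

    if context_filter == "ncptg":
        before = len(df)
        if reference is not None:
            keep = [
                classify_ncptg(r.chrom, int(r.pos), r.ref, r.alt, reference)
                for r in df.itertuples(index=False)
            ]
        elif "context" in df.columns:
            keep = [
                classify_ncptg_from_context(r.context, r.ref, r.alt)
                for r in df.itertuples(index=False)
            ]
        else:
            raise ValueError("ncptg filter needs a reference or a context column")
        df = df[np.asarray(keep, dtype=bool)]
        trail.append(f"N[C>T]pG context: removed {before - len(df)}")

    counts = df["lineage"].value_counts()
    return LineageCounts(
        s_shared=int(counts.get("shared", 0)),
        n_unique_a=int(counts.get("unique_a", 0)),
        n_unique_b=int(counts.get("unique_b", 0)),
        context_class=context_filter,
        provenance=trail,
    )


# ---------------------------------------------------------------------------
# burden
# ---------------------------------------------------------------------------

def burden_per_mb(
    snv_counts, indel_counts=None, genome_mb: float = GENOME_MB,
    snv_only: bool = False,
) -> float:
    """Mean small-variant burden per megabase across samples.

    The headline figure is the mean over samples of (SNV + indel) / genome
    size in Mb; ``snv_only=True`` computes the substitutions-only variant of
    the same summary.
    """
    if genome_mb <= 0:
        raise ValueError("genome_mb must be positive")
    snv = np.atleast_1d(np.asarray(snv_counts, dtype=float))
    if indel_counts is None or snv_only:
        indel = np.zeros_like(snv)
    else:
        indel = np.atleast_1d(np.asarray(indel_counts, dtype=float))
    if (snv < 0).any() or (indel < 0).any():
        raise ValueError("counts must be non-negative")
    return float(np.mean((snv + indel) / genome_mb))


# ---------------------------------------------------------------------------
# packaged case-study fixtures
# ---------------------------------------------------------------------------

def case_study_partition(context_class: str = "all_clonal") -> pd.DataFrame:
    """Synthetic partition tables encoding the twin case study's model inputs.

    Two deterministic fixtures, constructed (not measured) to carry the
    published count structure of the MPN twin pair:

    - ``all_clonal``: 7 shared + 91 twin-A-unique + 90 twin-B-unique
      lineage-restricted clonal SNVs;
    - ``ncptg``: 2 shared + 89 + 114 N[C>T]pG clock mutations, embedded among
      non-clock C>A calls that the context filter must remove.

    Positions, contexts and read counts are synthetic; every record passes
    the depth (40x) and multiplicity filters, shared records sit in the
    ancestral cluster 3 and twin-unique records in clusters 2 (A) and 1 (B),
    mirroring the cluster numbering of the case.
    """
    if context_class == "all_clonal":
        triple = (7, 91, 90)
        clock = False
        extra = (0, 0, 0)
    elif context_class == "ncptg":
        triple = (2, 89, 114)
        clock = True
        extra = (1, 10, 12)  # non-clock passengers the context filter removes
    else:
        raise ValueError(f"unknown context class: {context_class!r}")

    rows = []
    pos = 1000
    lineage_cluster = {"shared": 3, "unique_a": 2, "unique_b": 1}
    for lineage, n, n_extra in zip(["shared", "unique_a", "unique_b"], triple, extra):
        for i in range(n):
            rows.append({
                "chrom": "chrS", "pos": pos, "ref": "C", "alt": "T",
                "context": "ACG" if clock else "ACA",
                "lineage": lineage, "cluster": lineage_cluster[lineage],
                "depth_a": 40, "depth_b": 40, "multiplicity": 1,
            })
            pos += 100
        for i in range(n_extra):
            rows.append({
                "chrom": "chrS", "pos": pos, "ref": "C", "alt": "A",
                "context": "ACG", "lineage": lineage,
                "cluster": lineage_cluster[lineage],
                "depth_a": 40, "depth_b": 40, "multiplicity": 1,
            })
            pos += 100
    return pd.DataFrame(rows)


def case_study_lineage_labels() -> pd.DataFrame:
    """Pigeonhole labels for the case-study clusters (3 ancestral, 2/1 twin)."""
    return pd.DataFrame({
        "cluster": [3, 2, 1],
        "label": ["ancestral", "lineage_a", "lineage_b"],
    })
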