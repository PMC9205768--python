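"""Synthetic twin-pair somatic data with known lineage truth.

Generates data with the exact statistical structure the downstream pipeline
assumes: somatic mutations accrue as a Poisson process at a constant
per-genome rate ``lambda`` along a cell lineage that is shared between the
twins until ``t_mrca`` (years from fertilization) and then splits into two
independent lineages, one per twin, running until each twin's sampling time.
Read-level observations are drawn binomially from the expected variant allele
frequency implied by tumor purity, local copy number and mutation
multiplicity, and per-caller call sets add sensitivity dropouts and private
false calls.

All times are years from fertilization; calendar ages at sampling are offset
by a fixed gestation of 40 weeks (40 * 7 / 365.25 years).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GESTATION_YEARS = 40.0 * 7.0 / 365.25
"""Gestation offset added to postnatal ages: 40 weeks in 365.25-day years."""

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# parameters and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """World description for one simulated twin pair.

    Defaults follow the MPN twin-pair regime: a clock-like N[C>T]pG-scale
    mutation rate of ~2.5 per genome per year, an in utero split
    (t_mrca < gestation), ~40-year-old twins, 40x coverage and near-pure
    granulocyte samples.
    """

    rate_per_year: float = 2.5
    t_mrca_true: float = 0.6
    sampling_age_a: float = 40.0
    sampling_age_b: float = 40.0
    gestation_years: float = GESTATION_YEARS
    ncptg_fraction: float = 1.0
    depth_mean: float = 40.0
    purity_a: float = 0.95
    purity_b: float = 0.95
    caller_sensitivity: tuple[float, float, float] = (1.0, 1.0, 1.0)
    caller_false_calls: tuple[int, int, int] = (0, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_year < 0:
            raise ValueError("rate_per_year must be non-negative")
        if not 0.0 <= self.ncptg_fraction <= 1.0:
            raise ValueError("ncptg_fraction must lie in [0, 1]")
        for p in (self.purity_a, self.purity_b):
            if not 0.0 < p <= 1.0:
                raise ValueError("purity must lie in (0, 1]")
        for s in self.caller_sensitivity:
            if not 0.0 < s <= 1.0:
                raise ValueError("caller sensitivity must lie in (0, 1]")
        if any(f < 0 for f in self.caller_false_calls):
            raise ValueError("caller false-call counts must be >= 0")
        t_min = min(self.sampling_age_a, self.sampling_age_b) + self.gestation_years
        if not 0.0 < self.t_mrca_true < t_min:
            raise ValueError(
                f"t_mrca_true must lie in (0, {t_min:.3f}) years from fertilization"
            )

    @property
    def sampling_time_a(self) -> float:
        """Twin A sampling time in years from fertilization."""
        return self.sampling_age_a + self.gestation_years

    @property
    def sampling_time_b(self) -> float:
        return self.sampling_age_b + self.gestation_years


@dataclass
class SimulatedVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context: str  # reference trinucleotide centred on pos
    lineage: str  # 'shared' | 'unique_a' | 'unique_b'
    ccf: float = 1.0


@dataclass
class TwinTruth:
    """Ground-truth lineage partition with realized Poisson counts."""

    shared_mutations: list[SimulatedVariant]
    unique_a: list[SimulatedVariant]
    unique_b: list[SimulatedVariant]
    params: SimulationParams
    reference_path: Path | None = None

    @property
    def s(self) -> int:
        return len(self.shared_mutations)

    @property
    def n_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_b(self) -> int:
        return len(self.unique_b)

    def all_variants(self) -> list[SimulatedVariant]:
        return [*self.shared_mutations, *self.unique_a, *self.unique_b]

    def key_set(self, lineage: str) -> set[tuple[str, int, str, str]]:
        pool = {
            "shared": self.shared_mutations,
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
        }[lineage]
        return {(v.chrom, v.pos, v.ref, v.alt) for v in pool}


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------

def write_reference_fixture(
    path: str | Path,
    length_bp: int = 100_000,
    cpg_density: float = 0.02,
    seed: int = 0,
    chrom: str = "chrS",
    line_width: int = 70,
) -> Path:
    """Write a single-contig FASTA with a controlled CpG dinucleotide density.

    The sequence is drawn base by base; CG dinucleotides are planted at
    non-overlapping positions so that the realized CG frequency matches
    ``cpg_density`` (CG sites per bp) closely. Deterministic under ``seed``.
    """
    if length_bp < 1_000:
        raise ValueError("length_bp must be >= 1000")
    if not 0.0 <= cpg_density <= 0.25:
        raise ValueError("cpg_density must lie in [0, 0.25]")
    rng = np.random.default_rng(seed)
    seq = make_reference_sequence(length_bp, cpg_density, rng)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, length_bp, line_width):
            fh.write(seq[i : i + line_width] + "\n")
    # plain-text .fai so pyfaidx/pysam can open without writing next to fixtures
    return path


def make_reference_sequence(
    length_bp: int, cpg_density: float, rng: np.random.Generator
) -> str:
    """CpG-planted random sequence (no CG outside the planted sites)."""
    # background without C followed by G: draw bases, then break accidental CGs
    arr = rng.choice(_BASES, size=length_bp)
    cg = np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G"))
    while cg.size:
        arr[cg + 1] = rng.choice(np.array(["A", "C", "T"]), size=cg.size)
        cg = np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G"))
    n_sites = int(round(cpg_density * length_bp))
    if n_sites:
        # non-overlapping, non-adjacent starts at even offsets
        starts = rng.choice(length_bp // 2 - 1, size=n_sites, replace=False) * 2
        arr[starts] = "C"
        arr[starts + 1] = "G"
        # planting may create CG at starts-1 (X C) or starts+2; break those
        for off in (-1, 2):
            idx = starts + off
            idx = idx[(idx >= 0) & (idx < length_bp - 1)]
            bad = idx[(arr[idx] == "C") & (arr[idx + 1] == "G")]
            inner = np.isin(bad, starts) | np.isin(bad + 1, starts + 1)
            arr[bad[~inner]] = "A"
    return "".join(arr)


# ---------------------------------------------------------------------------
# lineage history
# ---------------------------------------------------------------------------

def simulate_twin_history(
    params: SimulationParams,
    reference: str | Path | None = None,
) -> TwinTruth:
    """Draw the twin pair's somatic mutation history.

    Counts are Poisson: ``s ~ Pois(rate * t_mrca)`` on the shared lineage and
    ``n_i ~ Pois(rate * (sampling_time_i - t_mrca))`` on each twin's private
    lineage. Each mutation gets a genomic position (uniform without
    replacement over the reference) and a substitution consistent with its
    context: with probability ``ncptg_fraction`` the site is a CpG cytosine
    mutated C>T, otherwise a non-CpG site with a random non-C>TpG change.

    When ``reference`` is None a 100 kb CpG-rich fixture sequence is generated
    in memory (not written to disk).
    """
    rng = np.random.default_rng(params.seed)
    lam = params.rate_per_year
    s = rng.poisson(lam * params.t_mrca_true)
    n_a = rng.poisson(lam * (params.sampling_time_a - params.t_mrca_true))
    n_b = rng.poisson(lam * (params.sampling_time_b - params.t_mrca_true))

    ref_path: Path | None = None
    if reference is None:
        seq = make_reference_sequence(100_000, 0.02, np.random.default_rng(params.seed + 1))
        chrom = "chrS"
    else:
        ref_path = Path(reference)
        chrom, seq = _read_single_fasta(ref_path)

    variants = _place_mutations(
        seq, chrom, [("shared", s), ("unique_a", n_a), ("unique_b", n_b)],
        params.ncptg_fraction, rng,
    )
    return TwinTruth(
        shared_mutations=[v for v in variants if v.lineage == "shared"],
        unique_a=[v for v in variants if v.lineage == "unique_a"],
        unique_b=[v for v in variants if v.lineage == "unique_b"],
        params=params,
        reference_path=ref_path,
    )


def _read_single_fasta(path: Path) -> tuple[str, str]:
    chrom = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                if chrom is not None:
                    break  # first contig only
                chrom = line[1:].split()[0]
            else:
                chunks.append(line.strip())
    if chrom is None:
        raise ValueError(f"no FASTA records in {path}")
    return chrom, "".join(chunks)


def _place_mutations(
    seq: str,
    chrom: str,
    lineage_counts: list[tuple[str, int]],
    ncptg_fraction: float,
    rng: np.random.Generator,
) -> list[SimulatedVariant]:
    """Assign distinct positions and alleles; collisions across lineages are
    impossible by construction (sampling without replacement)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    # CpG cytosines with both neighbors available
    cpg_c = np.flatnonzero((arr[:-1] == "C") & (arr[1:] == "G"))
    cpg_c = cpg_c[(cpg_c >= 1) & (cpg_c < len(arr) - 1)]
    interior = np.arange(1, len(arr) - 1)
    non_cpg = interior[~np.isin(interior, cpg_c)]
    # exclude sites whose C>T would still be NpCpG-like via a 5' C on a G
    total = sum(n for _, n in lineage_counts)
    if total == 0:
        return []
    is_clock = rng.random(total) < ncptg_fraction
    n_clock = int(is_clock.sum())
    if n_clock > cpg_c.size:
        raise ValueError("reference has too few CpG sites for requested mutations")
    if total - n_clock > non_cpg.size:
        raise ValueError("reference too short for requested mutation count")
    clock_pos = rng.choice(cpg_c, size=n_clock, replace=False)
    other_pos = rng.choice(non_cpg, size=total - n_clock, replace=False)

    variants: list[SimulatedVariant] = []
    ci = oi = 0
    idx = 0
    for lineage, n in lineage_counts:
        for _ in range(n):
            if is_clock[idx]:
                p = int(clock_pos[ci]); ci += 1
                ref, alt = "C", "T"
            else:
                p = int(other_pos[oi]); oi += 1
                ref = arr[p]
                choices = [b for b in "ACGT" if b != ref]
                # avoid making an accidental clock call (C>T before G cannot
                # happen off-CpG; G>A after C can — redraw alt in that case)
                if ref == "G" and p >= 1 and arr[p - 1] == "C":
                    choices = [b for b in choices if b != "A"]
                alt = choices[int(rng.integers(len(choices)))]
            context = "".join(arr[p - 1 : p + 2])
            variants.append(
                SimulatedVariant(chrom=chrom, pos=p + 1, ref=str(ref), alt=alt,
                                 context=context, lineage=lineage)
            )
            idx += 1
    return variants


# ---------------------------------------------------------------------------
# read-level observations
# ---------------------------------------------------------------------------

def expected_vaf(ccf: float, multiplicity: int, purity: float, cn_total: int,
                 cn_normal: int = 2) -> float:
    """Expected VAF = m * rho * CCF / (rho * CN_t + cn_normal * (1 - rho))."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    denom = purity * cn_total + cn_normal * (1.0 - purity)
    return multiplicity * purity * ccf / denom


def simulate_observations(
    truth: TwinTruth,
    depth_mean: float | None = None,
    purity: tuple[float, float] | None = None,
    cn_profile: int | dict[tuple[str, int], int] = 2,
    seed: int | None = None,
):
    """Draw per-twin read counts for every true variant.

    Returns a pandas DataFrame with one row per variant and per-twin columns
    ``alt_a/depth_a/alt_b/depth_b``. Depth ~ Poisson(depth_mean) truncated at
    1; alt reads ~ Binomial(depth, expected VAF); variants absent from a twin
    (the other twin's private lineage) have expected VAF 0 there.
    ``cn_profile`` is either a constant total copy number or a mapping
    (chrom, pos) -> CN_t (piecewise-constant segments resolved by caller).
    """
    import pandas as pd

    p = truth.params
    if depth_mean is None:
        depth_mean = p.depth_mean
    if purity is None:
        purity = (p.purity_a, p.purity_b)
    rng = np.random.default_rng(p.seed + 7 if seed is None else seed)

    rows = []
    for v in truth.all_variants():
        cn = cn_profile if isinstance(cn_profile, int) else cn_profile[(v.chrom, v.pos)]
        rec = {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
               "context": v.context, "lineage": v.lineage, "ccf": v.ccf,
               "cn_total": cn}
        for twin, rho in zip("ab", purity):
            present = v.lineage in ("shared", f"unique_{twin}")
            vaf = expected_vaf(v.ccf, 1, rho, cn) if present else 0.0
            depth = max(1, int(rng.poisson(depth_mean)))
            alt_reads = int(rng.binomial(depth, vaf))
            rec[f"alt_{twin}"] = alt_reads
            rec[f"depth_{twin}"] = depth
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "context", "lineage", "ccf",
                 "cn_total", "alt_a", "depth_a", "alt_b", "depth_b"],
    )


# ---------------------------------------------------------------------------
# per-caller VCF emission
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=twinclock-synthetic seed={seed}
##contig=<ID={chrom},length={length}>
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic mutation">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def emit_caller_callsets(
    observed,
    out_dir: str | Path,
    twin: str = "a",
    caller_sensitivity: tuple[float, float, float] = (1.0, 1.0, 1.0),
    caller_false_calls: tuple[int, int, int] = (0, 0, 0),
    seed: int = 0,
    contig_length: int = 100_000,
    callers: tuple[str, str, str] = ("mutect2", "strelka2", "octopus"),
) -> dict[str, Path]:
    """Write three per-caller somatic VCFs plus a germline VCF for one twin.

    Each variant called in this twin (alt reads > 0, or shared/unique-to-twin
    lineage) enters caller k's file with probability ``caller_sensitivity[k]``;
    false calls are private to one caller, never at a true variant position.
    Returns a dict caller -> path plus key 'germline'.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    present = observed[observed["lineage"].isin(["shared", f"unique_{twin}"])]
    chrom = observed["chrom"].iloc[0] if len(observed) else "chrS"
    used_pos = set(observed["pos"].tolist())
    header = _VCF_HEADER.format(seed=seed, chrom=chrom, length=contig_length)

    paths: dict[str, Path] = {}
    for k, caller in enumerate(callers):
        keep = rng.random(len(present)) < caller_sensitivity[k]
        records = []
        for (_, row), kept in zip(present.iterrows(), keep):
            if not kept:
                continue
            records.append(_vcf_record(row, twin))
        for _ in range(caller_false_calls[k]):
            pos = int(rng.integers(2, contig_length - 1))
            while pos in used_pos:
                pos = int(rng.integers(2, contig_length - 1))
            used_pos.add(pos)
            depth = max(1, int(rng.poisson(40)))
            alt_reads = max(1, int(rng.binomial(depth, 0.1)))
            records.append(
                f"{chrom}\t{pos}\t.\tA\tC\t30\tPASS\tSOMATIC\tGT:AD:DP\t"
                f"0/1:{depth - alt_reads},{alt_reads}:{depth}\t0/0:{depth},0:{depth}"
            )
        records.sort(key=lambda r: int(r.split("\t")[1]))
        path = out_dir / f"twin_{twin}.{caller}.vcf"
        path.write_text(header + "\n".join(records) + ("\n" if records else ""))
        paths[caller] = path

    germ = out_dir / f"twin_{twin}.germline.vcf"
    germ.write_text(header)  # interface placeholder: no germline SNPs simulated
    paths["germline"] = germ
    return paths


def _vcf_record(row, twin: str) -> str:
    alt_reads = int(row[f"alt_{twin}"])
    depth = int(row[f"depth_{twin}"])
    return (
        f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t60\t"
        f"PASS\tSOMATIC\tGT:AD:DP\t"
        f"0/1:{depth - alt_reads},{alt_reads}:{depth}\t"
        f"0/0:{depth},0:{depth}"
    )


def truth_table(truth: TwinTruth):
    """Truth as a DataFrame (chrom, pos, ref, alt, context, lineage, ccf)."""
    import pandas as pd

    return pd.DataFrame(
        [dataclasses.asdict(v) for v in truth.all_variants()],
        columns=["chrom", "pos", "ref", "alt", "context", "lineage", "ccf"],
    )
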