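"""Gene-level gain/loss calling from segmented, ploidy-corrected copy-number profiles.

Tumour copy-number profiles arrive as per-sample segments (chrom, start, end,
marker count, total copy number) together with an estimate of the sample's
overall ploidy.  Because osteosarcoma-like genomes are frequently polyploid,
gains and losses are defined *relative to ploidy*, not relative to 2n: a
segment is called gained when its copy number exceeds ploidy by more than
``delta`` (default 0.9 copies) and lost when it falls below ploidy by more
than ``delta``, provided the segment is supported by at least ``min_markers``
consecutive markers (default 10).

Segments dominated by telomeric/centromeric or segmental-duplication regions
(>50% overlap with a mask) are removed before calling.  Segment calls are
projected onto genes by the segment covering each gene's midpoint, recurrence
is assessed per gene across samples, and a permutation scorer delimits
significantly altered regions (a deliberately simple stand-in for dedicated
region-significance tools, whose lesion output can be read directly with
:func:`read_gistic_lesions`).

All internal coordinates are 0-based half-open.  SEG-format files on disk are
1-based inclusive and converted on read/write (see :mod:`cnmod.io`); BED is
read natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import bh_fdr

__all__ = [
    "GenomicInterval",
    "SegmentCall",
    "SampleProfile",
    "CallMatrix",
    "RegionScore",
    "RecurrenceResult",
    "RegionScanResult",
    "call_segment",
    "mask_segments",
    "gene_level_calls",
    "recurrence_filter",
    "score_regions",
    "genes_in_regions",
    "read_gistic_lesions",
]

# LogR threshold used only when exporting segment LogR ratios for an external
# region-significance run; never applied to internal total-copy-number calls.
LOGR_EXPORT_THRESHOLD = 0.12


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint or other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SegmentCall:
    """One copy-number segment of one sample."""

    sample_id: str
    interval: GenomicInterval
    n_markers: int
    total_cn: float

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")


@dataclass
class SampleProfile:
    """A sample's segmented profile plus its ploidy and aberrant cell fraction."""

    sample_id: str
    ploidy: float
    aberrant_cell_fraction: float
    segments: list[SegmentCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError("ploidy must be > 0")
        if not 0.0 <= self.aberrant_cell_fraction <= 1.0:
            raise ValueError("aberrant_cell_fraction must be in [0, 1]")
        self._check_non_overlapping()

    def _check_non_overlapping(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.interval.chrom, []).append(seg.interval)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError(
                        f"sample {self.sample_id}: overlapping segments on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )


class CallMatrix:
    """Gene-by-sample trinary calls (−1/0/+1) with the underlying copy numbers.

    Parameters
    ----------
    calls
        Integer DataFrame (genes x samples) with values in {−1, 0, +1}.
    cn
        Real DataFrame with identical index/columns holding total copy number.
    """

    def __init__(self, calls: pd.DataFrame, cn: pd.DataFrame):
        if not calls.index.equals(cn.index) or not calls.columns.equals(cn.columns):
            raise ValueError("calls and cn must share genes (index) and samples (columns)")
        if calls.index.has_duplicates:
            dupes = calls.index[calls.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        bad = ~calls.isin((-1, 0, 1)).to_numpy()
        if bad.any():
            raise ValueError("calls must be in {-1, 0, +1}")
        self.calls = calls.astype(np.int8)
        self.cn = cn.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallMatrix):
            return NotImplemented
        return self.calls.equals(other.calls) and self.cn.equals(other.cn)


@dataclass(frozen=True)
class RegionScore:
    """A significantly gained or lost genomic region with its score and q-value."""

    interval: GenomicInterval
    direction: str  # "gain" | "loss"
    score: float
    q: float

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be 'gain' or 'loss', got {self.direction!r}")
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")


def call_segment(
    seg: SegmentCall, ploidy: float, delta: float = 0.9, min_markers: int = 10
) -> int:
    """Call one segment gained (+1), lost (−1) or neutral (0) relative to ploidy.

    A call requires the copy number to deviate from ploidy by strictly more
    than ``delta`` copies AND the segment to contain at least ``min_markers``
    markers.  The boundary ``|cn − ploidy| == delta`` is neutral.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if seg.n_markers < min_markers:
        return 0
    dev = seg.total_cn - ploidy
    if dev > delta:
        return 1
    if -dev > delta:
        return -1
    return 0


def _merged(masks: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    """Union of mask intervals per chromosome as sorted disjoint tuples."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in masks:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [(s, e) for s, e in merged]
    return out


def mask_segments(
    profile: SampleProfile,
    masks: list[GenomicInterval],
    max_overlap: float = 0.5,
) -> SampleProfile:
    """Drop segments whose overlap with the mask union exceeds ``max_overlap``.

    The overlap fraction is (overlapped length) / (segment length), computed
    against the *union* of all masks; a segment overlapping exactly the
    threshold fraction is kept (strict ``>``).  Idempotent.
    """
    union = _merged(masks)
    kept = []
    for seg in profile.segments:
        ivs = union.get(seg.interval.chrom, [])
        ov = sum(
            max(0, min(seg.interval.end, e) - max(seg.interval.start, s)) for s, e in ivs
        )
        if ov / len(seg.interval) > max_overlap:
            continue
        kept.append(seg)
    return SampleProfile(
        sample_id=profile.sample_id,
        ploidy=profile.ploidy,
        aberrant_cell_fraction=profile.aberrant_cell_fraction,
        segments=kept,
    )


def _validate_genome_map(genome_map: pd.DataFrame) -> None:
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(genome_map.columns)
    if missing:
        raise ValueError(f"genome map missing columns: {sorted(missing)}")
    if genome_map["gene"].duplicated().any():
        dupes = genome_map.loc[genome_map["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene ids in genome map: {dupes[:5]}")


def gene_level_calls(
    profiles: list[SampleProfile],
    genome_map: pd.DataFrame,
    delta: float = 0.9,
    min_markers: int = 10,
) -> CallMatrix:
    """Project segment calls onto genes: each gene inherits the segment covering
    its midpoint.

    Genes with no covering segment are treated as unaltered at the sample's
    ploidy (cn = ploidy, call = 0).  Genes spanning a breakpoint take the call
    of the midpoint's segment.
    """
    _validate_genome_map(genome_map)
    genes = genome_map["gene"].tolist()
    mids = ((genome_map["start"].to_numpy() + genome_map["end"].to_numpy()) // 2).astype(
        np.int64
    )
    chroms = genome_map["chrom"].to_numpy()

    calls = np.zeros((len(genes), len(profiles)), dtype=np.int8)
    cn = np.zeros((len(genes), len(profiles)), dtype=float)
    for j, prof in enumerate(profiles):
        cn[:, j] = prof.ploidy
        by_chrom: dict[str, list[SegmentCall]] = {}
        for seg in prof.segments:
            by_chrom.setdefault(seg.interval.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.interval.start)
            starts = np.array([s.interval.start for s in segs])
            ends = np.array([s.interval.end for s in segs])
            sel = np.flatnonzero(chroms == chrom)
            if sel.size == 0:
                continue
            idx = np.searchsorted(starts, mids[sel], side="right") - 1
            for gi, si in zip(sel, idx):
                if si >= 0 and ends[si] > mids[gi]:
                    seg = segs[si]
                    cn[gi, j] = seg.total_cn
                    calls[gi, j] = call_segment(seg, prof.ploidy, delta, min_markers)
    samples = [p.sample_id for p in profiles]
    return CallMatrix(
        pd.DataFrame(calls, index=genes, columns=samples),
        pd.DataFrame(cn, index=genes, columns=samples),
    )


@dataclass
class RecurrenceResult:
    """Per-direction recurrent gene sets and the per-gene alteration frequencies."""

    gain_genes: set[str]
    loss_genes: set[str]
    frequencies: pd.DataFrame  # index gene, columns gain_freq / loss_freq


def recurrence_filter(cm: CallMatrix, min_freq: float = 0.20) -> RecurrenceResult:
    """Genes altered in at least ``min_freq`` of samples, per direction.

    A gene is gain-recurrent iff (#samples called +1) / n_samples >= min_freq,
    and loss-recurrent analogously (the threshold is inclusive).
    """
    if cm.shape[1] < 1:
        raise ValueError("need at least one sample")
    gain_freq = (cm.calls.to_numpy() == 1).mean(axis=1)
    loss_freq = (cm.calls.to_numpy() == -1).mean(axis=1)
    freq = pd.DataFrame(
        {"gain_freq": gain_freq, "loss_freq": loss_freq}, index=cm.calls.index
    )
    return RecurrenceResult(
        gain_genes=set(freq.index[gain_freq >= min_freq]),
        loss_genes=set(freq.index[loss_freq >= min_freq]),
        frequencies=freq,
    )


@dataclass
class RegionScanResult:
    """Output of :func:`score_regions`: regions plus the per-gene score table."""

    regions: list[RegionScore]
    gene_table: pd.DataFrame  # gene, chrom, start, end, {gain,loss}_{score,p,q}


def score_regions(
    cm: CallMatrix,
    profiles: list[SampleProfile],
    genome_map: pd.DataFrame,
    n_perm: int = 200,
    seed: int | None = None,
    q_threshold: float = 0.25,
) -> RegionScanResult:
    """Delimit significantly gained/lost regions by a cyclic-shift permutation test.

    Per gene and direction the score is the summed amplitude over samples,
    ``sum_s max(0, ±(cn_gs − ploidy_s))``.  The null preserves each sample's
    spatial autocorrelation by cyclically rotating its gene-order amplitude
    vector by an independent uniform offset per permutation.  Empirical
    p-values (fraction of null scores >= observed) are BH-adjusted per
    direction and maximal runs of genome-adjacent genes with q below
    ``q_threshold`` are reported as regions (score = peak gene score, q = the
    run's minimum).

    This scorer is a simple permutation surrogate for dedicated
    region-significance tools; their lesion output can be consumed directly
    via :func:`read_gistic_lesions` instead.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    _validate_genome_map(genome_map)
    gm = genome_map.reset_index(drop=True)
    cn = cm.cn.reindex(gm["gene"]).to_numpy()
    if np.isnan(cn).any():
        raise ValueError("genome map contains genes missing from the call matrix")
    ploidy = np.array([p.ploidy for p in profiles])
    order = {p.sample_id: i for i, p in enumerate(profiles)}
    ploidy = ploidy[[order[s] for s in cm.samples]]

    dev = cn - ploidy[None, :]
    n_genes, n_samples = dev.shape
    obs = {
        "gain": np.clip(dev, 0.0, None).sum(axis=1),
        "loss": np.clip(-dev, 0.0, None).sum(axis=1),
    }

    rng = np.random.default_rng(seed)
    exceed = {d: np.zeros(n_genes) for d in obs}
    rows = np.arange(n_genes)[:, None]
    cols = np.arange(n_samples)[None, :]
    for _ in range(n_perm):
        offsets = rng.integers(0, n_genes, size=n_samples)
        perm = dev[(rows - offsets[None, :]) % n_genes, cols]
        exceed["gain"] += np.clip(perm, 0.0, None).sum(axis=1) >= obs["gain"]
        exceed["loss"] += np.clip(-perm, 0.0, None).sum(axis=1) >= obs["loss"]

    table = gm[["gene", "chrom", "start", "end"]].copy()
    for d in ("gain", "loss"):
        p = exceed[d] / n_perm
        table[f"{d}_score"] = obs[d]
        table[f"{d}_p"] = p
        table[f"{d}_q"] = bh_fdr(p)

    regions: list[RegionScore] = []
    chrom_arr = table["chrom"].to_numpy()
    for d in ("gain", "loss"):
        sig = (table[f"{d}_q"] < q_threshold).to_numpy()
        i = 0
        while i < n_genes:
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n_genes and sig[j + 1] and chrom_arr[j + 1] == chrom_arr[i]:
                j += 1
            block = table.iloc[i : j + 1]
            regions.append(
                RegionScore(
                    interval=GenomicInterval(
                        chrom=chrom_arr[i],
                        start=int(block["start"].min()),
                        end=int(block["end"].max()),
                    ),
                    direction=d,
                    score=float(block[f"{d}_score"].max()),
                    q=float(block[f"{d}_q"].min()),
                )
            )
            i = j + 1
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.direction))
    return RegionScanResult(regions=regions, gene_table=table)


def genes_in_regions(regions: list[RegionScore], genome_map: pd.DataFrame) -> set[str]:
    """Genes whose midpoint falls inside any of the given regions."""
    _validate_genome_map(genome_map)
    mids = (genome_map["start"] + genome_map["end"]) // 2
    hit = pd.Series(False, index=genome_map.index)
    for r in regions:
        hit |= (
            (genome_map["chrom"] == r.interval.chrom)
            & (mids >= r.interval.start)
            & (mids < r.interval.end)
        )
    return set(genome_map.loc[hit, "gene"])


def read_gistic_lesions(path) -> list[RegionScore]:
    """Parse a GISTIC "all lesions" table into :class:`RegionScore` records.

    Expects the standard tab format with a ``Unique Name`` column containing
    "Amplification"/"Deletion", a peak-limits column like
    ``chr9:21967751-21995300(probes ...)`` (1-based inclusive; converted to
    0-based half-open) and a ``q values`` column.  Rows re-stating values in
    log units ("CN values") are skipped.  Malformed rows raise a parse error
    naming the file and line.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse GISTIC lesions file: {exc}") from exc

    def find_col(fragment: str) -> str:
        for c in df.columns:
            if fragment.lower() in c.lower():
                return c
        raise ValueError(f"{path}:1: missing column containing {fragment!r} in header")

    name_col = find_col("unique name")
    peak_col = find_col("peak limits")
    q_col = find_col("q value")

    out: list[RegionScore] = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        name = str(row[name_col])
        if "cn values" in name.lower():
            continue
        if "amplification" in name.lower():
            direction = "gain"
        elif "deletion" in name.lower():
            direction = "loss"
        else:
            raise ValueError(f"{path}:{lineno}: cannot infer direction from {name!r}")
        coord = str(row[peak_col]).split("(")[0].strip()
        try:
            chrom, span = coord.split(":")
            s, e = span.split("-")
            start, end = int(s) - 1, int(e)  # 1-based inclusive -> 0-based half-open
        except Exception as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates {coord!r}") from exc
        try:
            q = float(row[q_col])
        except Exception as exc:
            raise ValueError(f"{path}:{lineno}: malformed q value {row[q_col]!r}") from exc
        out.append(
            RegionScore(
                interval=GenomicInterval(chrom=chrom, start=start, end=end),
                direction=direction,
                score=0.0,
                q=q,
            )
        )
    return out
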