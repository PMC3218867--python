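"""Input/output and the shared marker-space coordinate system.

Segmented copy-number cohorts arrive as SEG-style tables in genomic (bp)
coordinates; every statistic downstream is computed in *marker space* — the
sorted list of probe positions per chromosome.  This module reads the standard
tab-delimited inputs (SEG, marker table, gene table, cytoband/arm table, BED
CNV masks), validates them, and projects segments onto markers.

Coordinate conventions: SEG and gene tables are 1-based inclusive bp; BED is
0-based half-open bp; all internal marker intervals are 0-based half-open
indices within a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerSet",
    "ArmTable",
    "CopyProfileSet",
    "normalize_chromosome",
    "read_seg",
    "read_markers",
    "read_gene_table",
    "read_arm_table",
    "project_to_markers",
    "profiles_to_seg",
    "exclude_cnv",
    "map_genes_to_markers",
    "write_score_track",
    "write_peak_table",
    "write_gene_scores",
    "write_event_catalog",
]

SEX_CHROMOSOMES = ("X", "Y")

#: default normalization of numeric aliases for the sex chromosomes
DEFAULT_CHROM_ALIASES = {"23": "X", "24": "Y"}


def normalize_chromosome(label, aliases: dict | None = None) -> str:
    """Normalize a chromosome label: strip a ``chr`` prefix, apply aliases.

    ``"chr7" -> "7"``, ``"23" -> "X"`` (alias table is explicit and
    overridable).
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    s = s.upper() if s.lower() in ("x", "y", "mt", "m") else s
    aliases = DEFAULT_CHROM_ALIASES if aliases is None else aliases
    return aliases.get(s, s)


def _chromosome_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass
class MarkerSet:
    """Sorted probe positions, the coordinate system for all scoring.

    Parameters
    ----------
    table
        DataFrame with columns ``marker``, ``chrom``, ``pos`` (bp).  Sorted
        on construction; positions must be strictly increasing within each
        chromosome.
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self):
        req = {"marker", "chrom", "pos"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"marker table needs columns {sorted(req)}")
        tab = self.table.copy()
        tab["chrom"] = tab["chrom"].map(normalize_chromosome)
        order = sorted(tab["chrom"].unique(), key=_chromosome_sort_key)
        tab["chrom"] = pd.Categorical(tab["chrom"], categories=order, ordered=True)
        tab = tab.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in tab.groupby("chrom", observed=True):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"duplicate or unsorted marker positions on chromosome {chrom}")
            self._index[str(chrom)] = pos
        tab["chrom"] = tab["chrom"].astype(str)
        self.table = tab

    @property
    def chromosomes(self) -> list[str]:
        return list(self._index)

    def positions(self, chrom: str) -> np.ndarray:
        return self._index[chrom]

    def n_markers(self, chrom: str) -> int:
        return len(self._index[chrom])

    def locate(self, chrom: str, start_bp: int, end_bp: int) -> tuple[int, int]:
        """Markers covered by the 1-based inclusive bp interval, as a
        0-based half-open marker-index interval."""
        pos = self._index[chrom]
        return int(np.searchsorted(pos, start_bp, "left")), int(
            np.searchsorted(pos, end_bp, "right")
        )

    def drop_sex_chromosomes(self) -> "MarkerSet":
        keep = ~self.table["chrom"].isin(SEX_CHROMOSOMES)
        return MarkerSet(self.table[keep].reset_index(drop=True))


@dataclass
class ArmTable:
    """Chromosome-arm boundaries; arms partition each chromosome.

    ``table`` columns: ``chrom``, ``arm`` (p/q), ``start``, ``end``
    (1-based inclusive bp).
    """

    table: pd.DataFrame

    def __post_init__(self):
        tab = self.table.copy()
        tab["chrom"] = tab["chrom"].map(normalize_chromosome)
        tab = tab.sort_values(["chrom", "start"]).reset_index(drop=True)
        self.table = tab

    def marker_arms(self, markers: MarkerSet, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-marker arm id (0-based) and per-arm marker counts.

        Every marker belongs to exactly one arm: boundaries clip to the
        marker range so arms always partition the chromosome.
        """
        pos = markers.positions(chrom)
        arms = self.table[self.table["chrom"] == chrom]
        if arms.empty:
            # no arm annotation: whole chromosome is a single arm
            return np.zeros(len(pos), dtype=np.intp), np.array([len(pos)])
        edges = arms["end"].to_numpy()[:-1]
        arm_id = np.searchsorted(edges, pos, "left")
        counts = np.bincount(arm_id, minlength=len(arms))
        return arm_id, counts


@dataclass
class CopyProfileSet:
    """Per-sample log2-ratio vectors in marker space, one matrix per
    chromosome (``n_samples`` x ``n_markers``)."""

    samples: list[str]
    markers: MarkerSet
    data: dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "CopyProfileSet":
        return CopyProfileSet(list(self.samples), self.markers, {c: a.copy() for c, a in self.data.items()})


# ---------------------------------------------------------------------------
# readers

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_markers", "seg_mean"]


def _has_header(first_fields: list[str]) -> bool:
    # a SEG header row has non-numeric start/end fields
    try:
        float(first_fields[2]), float(first_fields[3])
        return False
    except (ValueError, IndexError):
        return True


def read_seg(path, aliases: dict | None = None) -> pd.DataFrame:
    """Read a SEG-style tab-delimited file into a segment table.

    Columns: sample, chrom, start, end, n_markers, seg_mean; a header line
    is auto-detected.  Overlapping segments within one sample/chromosome are
    an error.
    """
    rows = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return pd.DataFrame(columns=_SEG_COLUMNS)
    start = 1 if _has_header(lines[0].split("\t")) else 0
    for lineno, ln in enumerate(lines[start:], start + 1):
        f = ln.split("\t")
        if len(f) < 6:
            raise ValueError(f"{path}: line {lineno}: expected >=6 tab-delimited fields, got {len(f)}")
        try:
            rows.append(
                (f[0], normalize_chromosome(f[1], aliases), int(f[2]), int(f[3]), int(float(f[4])), float(f[5]))
            )
        except ValueError as e:
            raise ValueError(f"{path}: line {lineno}: malformed row ({e})") from None
    seg = pd.DataFrame(rows, columns=_SEG_COLUMNS)
    bad = seg["start"] > seg["end"]
    if bad.any():
        raise ValueError(f"{path}: segment with start > end at data row {int(np.flatnonzero(bad)[0]) + 1}")
    _check_overlaps(seg, path)
    return seg


def _check_overlaps(seg: pd.DataFrame, path="<seg>") -> None:
    for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
        g = grp.sort_values("start")
        prev_end = g["end"].to_numpy()[:-1]
        nxt_start = g["start"].to_numpy()[1:]
        bad = np.flatnonzero(nxt_start <= prev_end)
        if bad.size:
            i = bad[0]
            a, b = g.iloc[i], g.iloc[i + 1]
            raise ValueError(
                f"{path}: overlapping segments for sample {sample} chromosome {chrom}: "
                f"[{a.start},{a.end}] and [{b.start},{b.end}]"
            )


def read_markers(path, aliases: dict | None = None, include_sex: bool = False) -> MarkerSet:
    """Read a 3-column marker table (name, chromosome, position)."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["marker", "chrom", "pos"], dtype={1: str})
    if len(tab) and not str(tab.iloc[0]["pos"]).strip().isdigit():
        tab = tab.iloc[1:].reset_index(drop=True)
    tab["pos"] = tab["pos"].astype(int)
    tab["chrom"] = tab["chrom"].map(lambda c: normalize_chromosome(c, aliases))
    ms = MarkerSet(tab)
    return ms if include_sex else ms.drop_sex_chromosomes()


def read_gene_table(path, markers: MarkerSet | None = None, aliases: dict | None = None) -> pd.DataFrame:
    """Read a 4-column gene table (gene, chromosome, start, end; 1-based bp).

    With ``markers`` given, adds the covered marker interval (``mstart``,
    ``mend``, half-open) and an ``unmapped`` flag.
    """
    tab = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["gene", "chrom", "start", "end"], dtype={1: str})
    if len(tab) and not str(tab.iloc[0]["start"]).strip().lstrip("-").isdigit():
        tab = tab.iloc[1:].reset_index(drop=True)
    tab["start"] = tab["start"].astype(int)
    tab["end"] = tab["end"].astype(int)
    tab["chrom"] = tab["chrom"].map(lambda c: normalize_chromosome(c, aliases))
    if (tab["start"] > tab["end"]).any():
        raise ValueError(f"{path}: gene interval with start > end")
    if markers is not None:
        tab = map_genes_to_markers(tab, markers)
    return tab


def map_genes_to_markers(genes: pd.DataFrame, markers: MarkerSet) -> pd.DataFrame:
    """Attach covered marker intervals to a gene table.

    A gene on an unknown chromosome, or covering zero markers, is flagged
    ``unmapped`` (with a warning for unknown chromosomes).
    """
    genes = genes.copy()
    mstart = np.zeros(len(genes), dtype=int)
    mend = np.zeros(len(genes), dtype=int)
    unmapped = np.zeros(len(genes), dtype=bool)
    known = set(markers.chromosomes)
    for i, row in enumerate(genes.itertuples(index=False)):
        if row.chrom not in known:
            warnings.warn(f"gene {row.gene}: unknown chromosome {row.chrom}; flagged unmapped")
            unmapped[i] = True
            continue
        s, e = markers.locate(row.chrom, row.start, row.end)
        mstart[i], mend[i] = s, e
        unmapped[i] = e <= s
    genes["mstart"], genes["mend"], genes["unmapped"] = mstart, mend, unmapped
    return genes


def read_arm_table(path, aliases: dict | None = None) -> ArmTable:
    """Read arm boundaries, either as an explicit arm table
    (chrom, arm, start, end) or a UCSC-style cytoband file
    (chrom, start, end, band, stain) whose bands are grouped by p/q."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if tab.shape[1] >= 5 or (tab.shape[1] >= 4 and tab.iloc[0, 3][:1] in "pq"):
        # cytoband layout: chrom, start(0-based), end, band, [stain]
        cyto = tab.iloc[:, :4].copy()
        cyto.columns = ["chrom", "start", "end", "band"]
        cyto["chrom"] = cyto["chrom"].map(lambda c: normalize_chromosome(c, aliases))
        cyto["start"] = cyto["start"].astype(int) + 1  # to 1-based inclusive
        cyto["end"] = cyto["end"].astype(int)
        cyto["arm"] = cyto["band"].str[0]
        rows = (
            cyto.groupby(["chrom", "arm"], sort=False)
            .agg(start=("start", "min"), end=("end", "max"))
            .reset_index()
        )
        return ArmTable(rows[["chrom", "arm", "start", "end"]])
    tab = tab.iloc[:, :4].copy()
    tab.columns = ["chrom", "arm", "start", "end"]
    tab["start"] = tab["start"].astype(int)
    tab["end"] = tab["end"].astype(int)
    return ArmTable(tab)


# ---------------------------------------------------------------------------
# projection

def project_to_markers(seg: pd.DataFrame, markers: MarkerSet) -> CopyProfileSet:
    """Project a segment table onto marker space.

    Each marker takes the ``seg_mean`` of its containing segment; markers in
    a gap between segments inherit the value of the nearest segment (left on
    ties); a sample missing a chromosome entirely is filled with 0.0 (with a
    warning).
    """
    _check_overlaps(seg)
    samples = list(dict.fromkeys(seg["sample"]))
    s_index = {s: i for i, s in enumerate(samples)}
    data = {c: np.zeros((len(samples), markers.n_markers(c))) for c in markers.chromosomes}
    seen = {c: np.zeros(len(samples), dtype=bool) for c in markers.chromosomes}
    for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
        chrom = str(chrom)
        if chrom not in data:
            continue
        si = s_index[sample]
        seen[chrom][si] = True
        pos = markers.positions(chrom)
        g = grp.sort_values("start")
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        means = g["seg_mean"].to_numpy()
        # nearest-segment assignment: midpoints between consecutive segments,
        # gap markers closer to the left segment's end go left (ties left)
        cuts = np.empty(len(starts) - 1)
        for k in range(len(starts) - 1):
            # marker belongs left iff pos - end_k <= start_{k+1} - pos
            cuts[k] = (ends[k] + starts[k + 1]) / 2.0
        idx = np.searchsorted(cuts, pos, "left")
        data[chrom][si] = means[idx]
    for chrom, flags in seen.items():
        if not flags.all():
            missing = [samples[i] for i in np.flatnonzero(~flags)]
            warnings.warn(
                f"chromosome {chrom}: no segments for sample(s) {missing[:5]}; filled with 0.0"
            )
    return CopyProfileSet(samples, markers, data)


def profiles_to_seg(profiles: CopyProfileSet) -> pd.DataFrame:
    """Run-length encode marker-space profiles back into a segment table.

    Breakpoints fall on marker positions, so projecting a marker-aligned
    segment table and re-encoding is an exact round trip.
    """
    rows = []
    for chrom, mat in profiles.data.items():
        pos = profiles.markers.positions(chrom)
        for si, sample in enumerate(profiles.samples):
            v = mat[si]
            edges = np.flatnonzero(np.diff(v) != 0) + 1
            starts = np.concatenate([[0], edges])
            ends = np.concatenate([edges, [len(v)]])
            for s, e in zip(starts, ends):
                rows.append((sample, chrom, int(pos[s]), int(pos[e - 1]), int(e - s), float(v[s])))
    return pd.DataFrame(rows, columns=_SEG_COLUMNS)


def exclude_cnv(profiles: CopyProfileSet, cnv_regions: pd.DataFrame) -> CopyProfileSet:
    """Mask germline-CNV regions out of the profiles.

    ``cnv_regions``: BED-style table (chrom, start, end; 0-based half-open
    bp).  Masked markers take the value of the left flanking unmasked marker
    (right flank at a chromosome start), joining the flanking segments so
    removal cannot create an artificial focal event.
    """
    if cnv_regions is None or len(cnv_regions) == 0:
        return profiles
    out = profiles.copy()
    cnv = cnv_regions.copy()
    cnv.columns = ["chrom", "start", "end"] + list(cnv.columns[3:])
    cnv["chrom"] = cnv["chrom"].map(normalize_chromosome)
    for chrom, grp in cnv.groupby("chrom", sort=False):
        if chrom not in out.data:
            continue
        pos = out.markers.positions(chrom)
        mask = np.zeros(len(pos), dtype=bool)
        for row in grp.itertuples(index=False):
            mask |= (pos > row.start) & (pos <= row.end)  # BED half-open, pos 1-based
        if mask.all():
            raise ValueError(f"CNV mask covers every marker on chromosome {chrom}")
        if not mask.any():
            continue
        keep = np.flatnonzero(~mask)
        # index of nearest unmasked marker to the left (fall back to right)
        left = np.searchsorted(keep, np.arange(len(pos)), "right") - 1
        src = keep[np.clip(left, 0, len(keep) - 1)]
        out.data[chrom][:, mask] = out.data[chrom][:, src[mask]]
    return out


# ---------------------------------------------------------------------------
# writers

def _write_with_header(path, df: pd.DataFrame, params: dict | None) -> None:
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_score_track(path, markers: MarkerSet, track, params: dict | None = None) -> None:
    """Write the per-marker score track: marker, chrom, pos, G_amp, G_del,
    -log10 q_amp, -log10 q_del."""
    tab = markers.table.copy()
    with np.errstate(divide="ignore"):
        tab["G_amp"] = np.concatenate([track.gscore_["amp"][c] for c in markers.chromosomes])
        tab["G_del"] = np.concatenate([track.gscore_["del"][c] for c in markers.chromosomes])
        tab["mlog10_q_amp"] = -np.log10(np.concatenate([track.qvalues_["amp"][c] for c in markers.chromosomes]))
        tab["mlog10_q_del"] = -np.log10(np.concatenate([track.qvalues_["del"][c] for c in markers.chromosomes]))
    _write_with_header(path, tab, params)


def write_peak_table(path, peaks: pd.DataFrame, params: dict | None = None) -> None:
    _write_with_header(path, peaks, params)


def write_gene_scores(path, gene_scores: pd.DataFrame, params: dict | None = None) -> None:
    _write_with_header(path, gene_scores, params)


def write_event_catalog(path, events: pd.DataFrame, markers: MarkerSet, params: dict | None = None) -> None:
    """Write the SCNA event catalog with both bp and marker coordinates."""
    ev = events.copy()
    ev["start_bp"] = [int(markers.positions(c)[s]) for c, s in zip(ev["chrom"], ev["start"])]
    ev["end_bp"] = [int(markers.positions(c)[e - 1]) for c, e in zip(ev["chrom"], ev["end"])]
    cols = ["sample", "chrom", "start_bp", "end_bp", "start", "end",
            "amp", "arm_fraction", "klass", "direction"]
    _write_with_header(path, ev[cols], params)
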