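"""Data model, file I/O and descriptive statistics for double-stranded methylation patterns.

A hairpin-bisulfite experiment reads out the methylation state of *both*
strands of a single DNA molecule at every CpG of a locus.  Each molecule is
therefore a pair of aligned binary vectors over the locus's CpG sites; which
of the two strands is the parent (template) strand and which is the newly
synthesized daughter strand is not observable.  This module holds the plain
data containers for such patterns, readers/writers for the simple text
formats used throughout the package, dyad classification (methylated /
hemimethylated / unmethylated), summary statistics in the style of a locus
summary table, a permutation test for spatial clustering of hemimethylated
dyads, and a small binomial helper for reasoning about PCR-crossover
artifacts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "MISSING",
    "CpGLocus",
    "DoubleStrandPattern",
    "DyadState",
    "DatasetSummary",
    "read_locus",
    "write_locus",
    "read_patterns",
    "write_patterns",
    "classify_dyads",
    "summarize_dataset",
    "adjacent_hemi_permutation_test",
    "crossover_probability",
]

#: sentinel for an unreadable (missing) strand entry in int8 strand vectors
MISSING: int = -1

_CHAR_TO_STATE = {"0": 0, "1": 1, "?": MISSING}
_STATE_TO_CHAR = {0: "0", 1: "1", MISSING: "?"}


class PatternParseError(ValueError):
    """Raised for malformed pattern or locus files (carries the line number)."""


@dataclass(frozen=True)
class CpGLocus:
    """A locus: an ordered set of CpG positions within a genomic region.

    ``cpg_positions`` are 1-based genomic coordinates of the cytosine of each
    CpG on the reference top strand; inter-site distances in bp (used by the
    HMM transition matrices) are differences of consecutive coordinates.
    """

    name: str
    chromosome: str
    cpg_positions: tuple[int, ...]
    region_start: int
    region_end: int

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.cpg_positions)
        object.__setattr__(self, "cpg_positions", pos)
        if len(pos) < 2:
            raise ValueError("a locus needs at least 2 CpG positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("CpG positions must be strictly increasing")
        if pos[0] < self.region_start or pos[-1] > self.region_end:
            raise ValueError("CpG positions must lie within [region_start, region_end]")

    @property
    def n_sites(self) -> int:
        return len(self.cpg_positions)

    @property
    def gaps(self) -> np.ndarray:
        """Distances in bp between consecutive CpG sites (length ``n_sites - 1``)."""
        return np.diff(np.asarray(self.cpg_positions))

    @property
    def median_gap(self) -> float:
        return float(np.median(self.gaps))


@dataclass
class DoubleStrandPattern:
    """One ascertained molecule: two aligned strand readouts, parentage unknown.

    Strand vectors are int8 arrays over {1 methylated, 0 unmethylated,
    -1 missing}, one entry per CpG site of the locus.  ``multiplicity`` counts
    identical ascertained molecules collapsed into one record.
    """

    pattern_id: str
    strand_a: np.ndarray
    strand_b: np.ndarray
    multiplicity: int = 1

    def __post_init__(self) -> None:
        self.strand_a = np.asarray(self.strand_a, dtype=np.int8)
        self.strand_b = np.asarray(self.strand_b, dtype=np.int8)
        if self.strand_a.shape != self.strand_b.shape or self.strand_a.ndim != 1:
            raise ValueError("strand vectors must be 1-D and of equal length")
        for v in (self.strand_a, self.strand_b):
            if not np.all(np.isin(v, (0, 1, MISSING))):
                raise ValueError("strand entries must be 0, 1 or missing (-1)")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")

    @property
    def n_sites(self) -> int:
        return int(self.strand_a.size)

    def swapped(self) -> "DoubleStrandPattern":
        """The same molecule with the (arbitrary) strand labels exchanged."""
        return DoubleStrandPattern(self.pattern_id, self.strand_b.copy(),
                                   self.strand_a.copy(), self.multiplicity)


class DyadState(enum.IntEnum):
    """Joint methylation state of one CpG dyad (both strands of one site)."""

    M = 0        # methylated on both strands
    HEMI_A = 1   # methyl on strand A only
    HEMI_B = 2   # methyl on strand B only
    U = 3        # unmethylated on both strands
    MISSING = 4  # at least one strand unreadable


@dataclass
class DatasetSummary:
    """Dataset-level descriptive statistics over scored (fully read) dyads."""

    n_patterns: int
    n_molecules: int
    n_dyads_scored: int
    pct_M: float
    pct_H: float
    pct_U: float
    hemi_run_counts: dict[int, int] = field(default_factory=dict)
    #: key 6 aggregates all runs of length >= 6
    MAX_RUN_BIN: int = 6


# ---------------------------------------------------------------------------
# file I/O

def write_locus(locus: CpGLocus, path: str | Path) -> None:
    doc = {
        "name": locus.name,
        "chromosome": locus.chromosome,
        "region_start": locus.region_start,
        "region_end": locus.region_end,
        "cpg_positions": list(locus.cpg_positions),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_locus(path: str | Path) -> CpGLocus:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return CpGLocus(
            name=str(doc["name"]),
            chromosome=str(doc["chromosome"]),
            cpg_positions=tuple(int(p) for p in doc["cpg_positions"]),
            region_start=int(doc["region_start"]),
            region_end=int(doc["region_end"]),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise PatternParseError(f"locus file {path} missing key {exc}") from exc


def _parse_strand(text: str, n_sites: int, lineno: int) -> np.ndarray:
    if len(text) != n_sites:
        raise PatternParseError(
            f"line {lineno}: strand string of length {len(text)}, "
            f"locus has {n_sites} CpG sites"
        )
    try:
        return np.array([_CHAR_TO_STATE[c] for c in text], dtype=np.int8)
    except KeyError as exc:
        raise PatternParseError(
            f"line {lineno}: illegal strand character {exc.args[0]!r}"
        ) from exc


def read_patterns(path: str | Path, locus: CpGLocus) -> list[DoubleStrandPattern]:
    """Read a pattern TSV (``pattern_id  strand_a  strand_b  count``).

    '#'-prefixed lines are comments; a header line naming the columns is
    accepted and skipped.  Strand strings are over ``{0, 1, ?}`` and must
    match the locus's CpG count.
    """
    patterns: list[DoubleStrandPattern] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "pattern_id":
                continue
            if len(fields) not in (3, 4):
                raise PatternParseError(
                    f"line {lineno}: expected 3 or 4 tab-separated fields, got {len(fields)}"
                )
            pid, sa, sb = fields[0], fields[1], fields[2]
            try:
                count = int(fields[3]) if len(fields) == 4 else 1
            except ValueError as exc:
                raise PatternParseError(f"line {lineno}: bad count {fields[3]!r}") from exc
            if count < 1:
                raise PatternParseError(f"line {lineno}: count must be >= 1")
            patterns.append(
                DoubleStrandPattern(
                    pattern_id=pid,
                    strand_a=_parse_strand(sa, locus.n_sites, lineno),
                    strand_b=_parse_strand(sb, locus.n_sites, lineno),
                    multiplicity=count,
                )
            )
    return patterns


def write_patterns(patterns: Iterable[DoubleStrandPattern], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pattern_id\tstrand_a\tstrand_b\tcount\n")
        for p in patterns:
            sa = "".join(_STATE_TO_CHAR[int(v)] for v in p.strand_a)
            sb = "".join(_STATE_TO_CHAR[int(v)] for v in p.strand_b)
            fh.write(f"{p.pattern_id}\t{sa}\t{sb}\t{p.multiplicity}\n")


# ---------------------------------------------------------------------------
# dyad classification and summaries

def classify_dyads(pattern: DoubleStrandPattern) -> np.ndarray:
    """Per-site dyad states as an int8 vector of :class:`DyadState` codes.

    A site with a missing entry on either strand is labelled MISSING.
    Swapping the two strand labels exchanges HEMI_A and HEMI_B and fixes
    M and U.
    """
    a, b = pattern.strand_a, pattern.strand_b
    out = np.full(a.size, DyadState.MISSING, dtype=np.int8)
    scored = (a != MISSING) & (b != MISSING)
    out[scored & (a == 1) & (b == 1)] = DyadState.M
    out[scored & (a == 1) & (b == 0)] = DyadState.HEMI_A
    out[scored & (a == 0) & (b == 1)] = DyadState.HEMI_B
    out[scored & (a == 0) & (b == 0)] = DyadState.U
    return out


def _hemi_runs(dyads: np.ndarray) -> list[int]:
    """Lengths of maximal runs (>= 2) of consecutive same-orientation hemis."""
    runs: list[int] = []
    run_len = 0
    run_state = -2
    for d in dyads:
        if d in (DyadState.HEMI_A, DyadState.HEMI_B) and d == run_state:
            run_len += 1
        else:
            if run_len >= 2:
                runs.append(run_len)
            if d in (DyadState.HEMI_A, DyadState.HEMI_B):
                run_state, run_len = int(d), 1
            else:
                run_state, run_len = -2, 0
    if run_len >= 2:
        runs.append(run_len)
    return runs


def summarize_dataset(patterns: Sequence[DoubleStrandPattern],
                      locus: CpGLocus) -> DatasetSummary:
    """Dyad-class percentages and same-orientation hemi-run counts.

    Percentages are over all scored dyads, weighted by pattern multiplicity.
    A hemi run is a maximal stretch of >= 2 consecutive (in site order)
    hemimethylated dyads whose methyl groups all sit on the same strand; any
    non-hemi, missing or opposite-orientation dyad breaks a run.  Run counts
    are binned at lengths 2, 3, 4, 5 and >= 6 (key 6).
    """
    if not patterns:
        raise ValueError("cannot summarize an empty dataset")
    counts = np.zeros(4, dtype=np.int64)  # M, H_a, H_b, U
    run_counts = {k: 0 for k in (2, 3, 4, 5, 6)}
    n_molecules = 0
    for p in patterns:
        if p.n_sites != locus.n_sites:
            raise ValueError(f"pattern {p.pattern_id}: length does not match locus")
        dy = classify_dyads(p)
        w = p.multiplicity
        n_molecules += w
        for cls in range(4):
            counts[cls] += w * int(np.sum(dy == cls))
        for run in _hemi_runs(dy):
            run_counts[min(run, 6)] += w
    scored = int(counts.sum())
    if scored == 0:
        raise ValueError("dataset has no scored dyads")
    pct = 100.0 * counts / scored
    return DatasetSummary(
        n_patterns=len(patterns),
        n_molecules=n_molecules,
        n_dyads_scored=scored,
        pct_M=float(pct[0]),
        pct_H=float(pct[1] + pct[2]),
        pct_U=float(pct[3]),
        hemi_run_counts=run_counts,
    )


# ---------------------------------------------------------------------------
# permutation test for clustering of hemimethylated dyads

def _adjacent_hemi_stat(dyad_rows: list[np.ndarray]) -> int:
    """Number of adjacent site pairs where both dyads are same-orientation hemis."""
    stat = 0
    for dy in dyad_rows:
        hemi = (dy == DyadState.HEMI_A) | (dy == DyadState.HEMI_B)
        same = hemi[:-1] & hemi[1:] & (dy[:-1] == dy[1:])
        stat += int(np.sum(same))
    return stat


def adjacent_hemi_permutation_test(patterns: Sequence[DoubleStrandPattern],
                                   locus: CpGLocus,
                                   n_perm: int = 2000,
                                   seed: int = 0) -> float:
    """Permutation test for spatial clustering of same-orientation hemis.

    Observed statistic: over all molecules, the number of adjacent CpG pairs
    at which both dyads are hemimethylated with the methyl on the same
    strand.  The null shuffles each molecule's dyad sequence across site
    order independently, which preserves per-molecule dyad composition while
    destroying spatial adjacency.  Returns the upper-tail p-value with the
    add-one convention ``(1 + #{null >= obs}) / (1 + n_perm)``, so p is
    always in (0, 1].

    This is a reconstruction of an adjacent-site correlation test; the
    statistic targets exactly the feature (runs of same-orientation hemis)
    that carries the processivity signal.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    for p in patterns:
        dy = classify_dyads(p)
        rows.extend(dy.copy() for _ in range(p.multiplicity))
    obs = _adjacent_hemi_stat(rows)
    hits = 0
    for _ in range(n_perm):
        perm_rows = [rng.permutation(dy) for dy in rows]
        if _adjacent_hemi_stat(perm_rows) >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# PCR-crossover binomial helper

def crossover_probability(n_molecules: int, per_molecule_rate: float,
                          n_crossovers: int = 1) -> float:
    """P(at least one of ``n_molecules`` arose from ``n_crossovers`` template switches).

    Each ascertained molecule independently is a ``n_crossovers``-fold
    crossover artifact with probability ``per_molecule_rate ** n_crossovers``;
    the result is the binomial probability of at least one such molecule,
    ``1 - (1 - rate**k) ** n``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if not 0.0 <= per_molecule_rate <= 1.0:
        raise ValueError("per_molecule_rate must be in [0, 1]")
    if n_crossovers < 1:
        raise ValueError("n_crossovers must be >= 1")
    p_event = per_molecule_rate ** n_crossovers
    return float(1.0 - (1.0 - p_event) ** n_molecules)


def summary_to_tsv(summary: DatasetSummary) -> str:
    """Render a :class:`DatasetSummary` as a two-column TSV report."""
    lines = [
        f"n_patterns\t{summary.n_patterns}",
        f"n_molecules\t{summary.n_molecules}",
        f"n_dyads_scored\t{summary.n_dyads_scored}",
        f"pct_methylated\t{summary.pct_M:.1f}",
        f"pct_hemimethylated\t{summary.pct_H:.1f}",
        f"pct_unmethylated\t{summary.pct_U:.1f}",
    ]
    for k in (2, 3, 4, 5):
        lines.append(f"runs_of_{k}_hemis\t{summary.hemi_run_counts.get(k, 0)}")
    lines.append(f"runs_of_6plus_hemis\t{summary.hemi_run_counts.get(6, 0)}")
    return "\n".join(lines) + "\n"
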