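"""Directons and randomization tests for chromosomal defense-gene clustering.

Distances are measured in gene-index units (minimum-arc distance on
circular replicons): the randomization samples genes, so index units make
the null exchangeable. The co-localization test compares the observed
median nearest-neighbor distance among defense units (genes or directons)
with the same statistic over uniform without-replacement samples of equal
size; the one-sided p-value uses the add-one correction
``p = (1 + #{null <= observed}) / (1 + n_reps)``.

A directon is a maximal run of consecutive co-directed genes (an operon
proxy); on a circular replicon the first and last run merge when
co-directed. A directon is defense-flagged if at least one of its genes
belongs to a defense system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import CLASS_VOCABULARY, NON_DEFENSE, ValidationError

logger = logging.getLogger("genomeflux")

__all__ = [
    "ChromosomeMap",
    "DirectonSet",
    "ColocalizationResult",
    "build_directons",
    "nearest_neighbor_median",
    "colocalization_test",
    "event_colocalization_test",
    "read_gene_maps",
    "write_gene_maps",
    "gene_map_from_gff_like",
]


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class ChromosomeMap:
    """Ordered, stranded gene list of one replicon."""

    replicon_id: str
    circular: bool
    strands: np.ndarray      # '+' / '-' per gene, in chromosomal order
    family_ids: np.ndarray   # family ID per gene
    classes: np.ndarray      # defense class or 'non-defense' per gene

    def __post_init__(self):
        self.strands = np.asarray(self.strands, dtype=object)
        self.family_ids = np.asarray(self.family_ids, dtype=object)
        self.classes = np.asarray(self.classes, dtype=object)
        n = len(self.strands)
        if n < 1:
            raise ValidationError("chromosome map needs at least 1 gene")
        if len(self.family_ids) != n or len(self.classes) != n:
            raise ValidationError("strand/family/class arrays must align")
        if not set(self.strands) <= {"+", "-"}:
            raise ValidationError("strands must be '+' or '-'")
        bad = set(self.classes) - set(CLASS_VOCABULARY)
        if bad:
            raise ValidationError(f"unknown gene classes: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return len(self.strands)

    @property
    def defense_mask(self) -> np.ndarray:
        return self.classes != NON_DEFENSE

    @property
    def defense_positions(self) -> np.ndarray:
        return np.flatnonzero(self.defense_mask)

    def rotated(self, offset: int) -> "ChromosomeMap":
        """The same circular replicon with a shifted origin."""
        if not self.circular:
            raise ValidationError("only circular replicons can be rotated")
        idx = (np.arange(self.n_genes) + offset) % self.n_genes
        return ChromosomeMap(self.replicon_id, True, self.strands[idx],
                             self.family_ids[idx], self.classes[idx])


@dataclass
class DirectonSet:
    """Maximal co-directed runs of a chromosome, in chromosomal order."""

    replicon_id: str
    circular: bool
    members: list[np.ndarray]        # gene indices per directon
    strands: list[str]
    defense_flags: np.ndarray = field(default=None)

    @property
    def n_directons(self) -> int:
        return len(self.members)

    @property
    def defense_positions(self) -> np.ndarray:
        return np.flatnonzero(self.defense_flags)

    def directon_of_gene(self) -> np.ndarray:
        """Gene index -> directon index."""
        n_genes = sum(len(m) for m in self.members)
        out = np.empty(n_genes, dtype=int)
        for d, m in enumerate(self.members):
            out[m] = d
        return out


@dataclass(frozen=True)
class ColocalizationResult:
    replicon_id: str
    level: str                     # 'gene' or 'directon'
    observed_median: float
    p_value: float
    n_reps: int
    seed: int
    n_units: int
    n_defense_units: int
    degenerate: bool = False


# --------------------------------------------------------------------------
# Directons
# --------------------------------------------------------------------------

def build_directons(cmap: ChromosomeMap) -> DirectonSet:
    """Partition the gene order into maximal co-directed runs."""
    strands = cmap.strands
    n = cmap.n_genes
    breaks = np.flatnonzero(strands[1:] != strands[:-1]) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [n]])
    members = [np.arange(s, e) for s, e in zip(starts, ends)]
    run_strands = [str(strands[s]) for s in starts]
    if cmap.circular and len(members) > 1 and run_strands[0] == run_strands[-1]:
        members[0] = np.concatenate([members[-1], members[0]])
        members = members[:-1]
        run_strands = run_strands[:-1]
    defense = cmap.defense_mask
    flags = np.array([bool(defense[m].any()) for m in members])
    return DirectonSet(cmap.replicon_id, cmap.circular, members, run_strands,
                       flags)


# --------------------------------------------------------------------------
# Nearest-neighbor median distance
# --------------------------------------------------------------------------

def _nn_median_rows(pos: np.ndarray, n: int, circular: bool) -> np.ndarray:
    """Median nearest-neighbor distance per row of sorted positions.

    *pos* is (n_rows, k) with each row sorted ascending; distances are in
    index units, minimum-arc when circular.
    """
    k = pos.shape[1]
    gaps = np.diff(pos, axis=1)
    if circular:
        wrap = (n - (pos[:, -1] - pos[:, 0]))[:, None]
        left = np.concatenate([wrap, gaps], axis=1)       # gap to predecessor
        right = np.concatenate([gaps, wrap], axis=1)      # gap to successor
    else:
        inf = np.full((pos.shape[0], 1), np.inf)
        left = np.concatenate([inf, gaps], axis=1)
        right = np.concatenate([gaps, inf], axis=1)
    nn = np.minimum(left, right)
    return np.median(nn, axis=1)


def nearest_neighbor_median(positions: Iterable[int], n: int,
                            circular: bool = True) -> float:
    """Median over positions of the distance to the closest other position."""
    pos = np.unique(np.asarray(list(positions), dtype=int))
    if len(pos) < 2:
        raise ValidationError("need at least 2 positions")
    if pos.min() < 0 or pos.max() >= n:
        raise ValidationError("positions must lie in [0, n)")
    return float(_nn_median_rows(pos[None, :], n, circular)[0])


# --------------------------------------------------------------------------
# Randomization tests
# --------------------------------------------------------------------------

def _randomization_p(observed: float, k: int, pool: np.ndarray, n_units: int,
                     circular: bool, n_reps: int,
                     rng: np.random.Generator) -> float:
    """One-sided p for clustering: null = k uniform draws from *pool*."""
    # without-replacement row-wise sampling via random-key argsort
    keys = rng.random((n_reps, len(pool)))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    samples = np.sort(pool[idx], axis=1)
    null = _nn_median_rows(samples, n_units, circular)
    return float((1 + np.sum(null <= observed)) / (1 + n_reps))


def colocalization_test(cmap: ChromosomeMap, level: str = "gene",
                        n_reps: int = 10_000, seed: int = 0,
                        ) -> ColocalizationResult:
    """Are defense units closer together than chance expectation?

    Observed statistic: median nearest-neighbor distance among defense
    units (genes, or defense-flagged directons). Null: the same statistic
    for equally many units sampled uniformly without replacement from all
    units of the replicon.
    """
    if level not in ("gene", "directon"):
        raise ValidationError("level must be 'gene' or 'directon'")
    if level == "gene":
        n_units = cmap.n_genes
        defense = cmap.defense_positions
    else:
        ds = build_directons(cmap)
        n_units = ds.n_directons
        defense = ds.defense_positions
    k = len(defense)
    if k < 2:
        raise ValidationError("need at least 2 defense units")
    if k == n_units:
        logger.warning("%s: all units are defense; test degenerate",
                       cmap.replicon_id)
        obs = nearest_neighbor_median(defense, n_units, cmap.circular)
        return ColocalizationResult(cmap.replicon_id, level, obs, 1.0,
                                    n_reps, seed, n_units, k, degenerate=True)
    observed = nearest_neighbor_median(defense, n_units, cmap.circular)
    rng = np.random.default_rng(seed)
    p = _randomization_p(observed, k, np.arange(n_units), n_units,
                         cmap.circular, n_reps, rng)
    return ColocalizationResult(cmap.replicon_id, level, observed, p,
                                n_reps, seed, n_units, k)


def event_colocalization_test(event_positions: Sequence[int],
                              cmap: ChromosomeMap, level: str = "gene",
                              n_reps: int = 10_000, seed: int = 0,
                              ) -> ColocalizationResult:
    """Are gain/loss events clustered among the defense genes?

    *event_positions* are gene indices with an inferred event on a
    terminal branch; they must be a subset of the replicon's defense gene
    positions. The null resamples equally many units from the defense
    units (not from all genes).
    """
    if level not in ("gene", "directon"):
        raise ValidationError("level must be 'gene' or 'directon'")
    events = np.unique(np.asarray(list(event_positions), dtype=int))
    defense = cmap.defense_positions
    if not np.isin(events, defense).all():
        raise ValidationError("event positions must be defense gene positions")
    if level == "gene":
        n_units = cmap.n_genes
        pool = defense
        event_units = events
    else:
        ds = build_directons(cmap)
        n_units = ds.n_directons
        gene2dir = ds.directon_of_gene()
        pool = ds.defense_positions
        event_units = np.unique(gene2dir[events])
    k = len(event_units)
    if k < 2:
        raise ValidationError("need at least 2 event units")
    observed = nearest_neighbor_median(event_units, n_units, cmap.circular)
    if k == len(pool):
        logger.warning("%s: events cover all defense units; test degenerate",
                       cmap.replicon_id)
        return ColocalizationResult(cmap.replicon_id, level, observed, 1.0,
                                    n_reps, seed, n_units, k, degenerate=True)
    rng = np.random.default_rng(seed)
    p = _randomization_p(observed, k, pool, n_units, cmap.circular,
                         n_reps, rng)
    return ColocalizationResult(cmap.replicon_id, level, observed, p,
                                n_reps, seed, n_units, k)


# --------------------------------------------------------------------------
# Gene-map IO
# --------------------------------------------------------------------------

def write_gene_maps(maps: Iterable[ChromosomeMap], path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write replicon gene maps as TSV with per-replicon circularity headers."""
    maps = list(maps)
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        for m in maps:
            fh.write(f"# replicon={m.replicon_id} circular={int(m.circular)}\n")
        fh.write("replicon\tindex\tstrand\tfamily_id\tclass\n")
        for m in maps:
            for i in range(m.n_genes):
                fh.write(f"{m.replicon_id}\t{i}\t{m.strands[i]}"
                         f"\t{m.family_ids[i]}\t{m.classes[i]}\n")


def read_gene_maps(path: str | Path) -> list[ChromosomeMap]:
    """Read gene-map TSV; replicons default to circular unless the header
    says otherwise (bacterial chromosomes are circular)."""
    circ: dict[str, bool] = {}
    rows = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = dict(
                    p.split("=", 1) for p in line.lstrip("# ").split()
                    if "=" in p
                )
                if "replicon" in parts:
                    circ[parts["replicon"]] = parts.get("circular", "1") in (
                        "1", "true", "True")
                continue
            if line:
                rows.append(line.split("\t"))
    if not rows or rows[0][:5] != ["replicon", "index", "strand", "family_id",
                                   "class"]:
        raise ValidationError("gene-map TSV needs columns: replicon, index, "
                              "strand, family_id, class")
    frame = pd.DataFrame(rows[1:], columns=rows[0][:5])
    frame["index"] = frame["index"].astype(int)
    out = []
    for rid, grp in frame.groupby("replicon", sort=False):
        grp = grp.sort_values("index")
        if not np.array_equal(grp["index"].to_numpy(), np.arange(len(grp))):
            raise ValidationError(f"replicon {rid}: indices must be 0..n-1")
        out.append(ChromosomeMap(
            replicon_id=str(rid), circular=circ.get(str(rid), True),
            strands=grp["strand"].to_numpy(),
            family_ids=grp["family_id"].to_numpy(),
            classes=grp["class"].to_numpy(),
        ))
    return out


def gene_map_from_gff_like(path: str | Path, circular: bool = True,
                           ) -> list[ChromosomeMap]:
    """Convert minimal GFF-like input into gene maps, ordered by start.

    Expected columns (tab-separated, '#' comments ignored): seqid, start,
    strand, attributes; attributes hold ``family_id=...`` and optionally
    ``class=...`` (semicolon-separated). Nine-column GFF3 lines also work:
    seqid / start / strand / attributes are taken from columns 1, 4, 7, 9.
    """
    records = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 9:
                seqid, start, strand, attrs = parts[0], parts[3], parts[6], parts[8]
            elif len(parts) >= 4:
                seqid, start, strand, attrs = parts[0], parts[1], parts[2], parts[3]
            else:
                raise ValidationError(f"unparseable GFF-like line: {line!r}")
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "family_id" not in fields:
                raise ValidationError("attributes must include family_id=")
            records.append((seqid, int(start), strand,
                            fields["family_id"],
                            fields.get("class", NON_DEFENSE)))
    if not records:
        raise ValidationError("no gene records found")
    frame = pd.DataFrame(records, columns=["seqid", "start", "strand",
                                           "family_id", "class"])
    out = []
    for rid, grp in frame.groupby("seqid", sort=False):
        grp = grp.sort_values("start", kind="stable")
        out.append(ChromosomeMap(
            replicon_id=str(rid), circular=circular,
            strands=grp["strand"].to_numpy(),
            family_ids=grp["family_id"].to_numpy(),
            classes=grp["class"].to_numpy(),
        ))
    return out
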