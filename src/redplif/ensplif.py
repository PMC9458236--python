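"""Ensemble aggregation of per-pose fingerprints into ensPLIF descriptors.

For each compound, all docking poses across the receptor ensemble ×
replicates × modes are fingerprinted, and descriptor ``N`` (column ``VN``)
is the fraction of aggregated poses in which bit ``N`` is set.  With the
standard protocol of 2 receptor clusters × 3 replicates × 5 modes every
fraction has denominator 30.

The analysis table has one row per compound with columns
``y, name, dg, V1..Vn``: the binary activity label, the compound name, the
mean over runs of each run's best docking score (kcal/mol), and the
fraction descriptors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mol_io import Molecule, PoseSet
from .plif import BITS_PER_RESIDUE, Bitstring, GeometryParams, compute_plif

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundDockingResult",
    "aggregate",
    "compound_dg",
    "filter_poses_by_score",
    "compound_fractions",
    "build_table",
    "write_table",
    "read_table",
    "descriptor_columns",
]


@dataclass
class CompoundDockingResult:
    """All docking runs of one compound against the receptor ensemble.

    ``runs`` holds ``(receptor_id, replicate_index, PoseSet)`` triples; the
    expected count is n_receptors × n_replicates (6 for the standard 2 × 3
    protocol) and deviations are logged, not rejected.
    """

    name: str
    runs: list[tuple[str, int, PoseSet]]
    label: int | None = None

    def all_scores(self) -> list[float]:
        return [s for _, _, ps in self.runs for s in ps.scores]

    def check_run_count(self, n_receptors: int = 2, n_replicates: int = 3) -> bool:
        expected = n_receptors * n_replicates
        if len(self.runs) != expected:
            logger.warning("%s: %d runs, expected %d", self.name, len(self.runs), expected)
            return False
        return True


def aggregate(bitstrings: list[Bitstring]) -> np.ndarray:
    """Per-bit fraction of poses showing the bit: V[i] = k_i / m.

    All fingerprints must share the residue list; empty input raises.
    Permutation-invariant, and merging pose sets merges as the weighted
    mean ``(|A|·V_A + |B|·V_B) / (|A|+|B|)``.
    """
    if not bitstrings:
        raise ValueError("cannot aggregate zero fingerprints")
    ref = bitstrings[0].residue_list
    for b in bitstrings[1:]:
        if b.residue_list != ref or b.bits.size != bitstrings[0].bits.size:
            raise ValueError("all fingerprints must share one residue list")
    stack = np.array([b.bits for b in bitstrings], dtype=float)
    return stack.mean(axis=0)


def compound_dg(result: CompoundDockingResult) -> float:
    """Average docking score: mean over runs of each run's best (lowest) score."""
    best = [min(ps.scores) for _, _, ps in result.runs if len(ps.scores)]
    if not best:
        raise ValueError(f"{result.name}: no poses to score")
    return float(np.mean(best))


def filter_poses_by_score(result: CompoundDockingResult, cutoff: float) -> CompoundDockingResult:
    """Retain only poses with score ≤ ``cutoff`` kcal/mol.

    A compound may be left with zero poses; downstream its descriptor row
    becomes all-zero and is flagged in the log.
    """
    runs: list[tuple[str, int, PoseSet]] = []
    for rid, rep, ps in result.runs:
        kept = [(p, s) for p, s in zip(ps.poses, ps.scores) if s <= cutoff]
        if kept:
            poses, scores = zip(*kept)
            runs.append((rid, rep, PoseSet(list(poses), list(scores), ps.source_tag)))
    return CompoundDockingResult(name=result.name, runs=runs, label=result.label)


def compound_fractions(
    result: CompoundDockingResult,
    receptors: dict[str, Molecule],
    residue_list,
    nobb: bool = True,
    params: GeometryParams | None = None,
) -> np.ndarray:
    """Fingerprint every pose of one compound and aggregate to fractions."""
    bitstrings = []
    for rid, _, ps in result.runs:
        receptor = receptors[rid]
        for pose in ps.poses:
            bitstrings.append(compute_plif(receptor, pose, residue_list, nobb=nobb, params=params))
    return aggregate(bitstrings)


def descriptor_columns(n_bits: int) -> list[str]:
    return [f"V{i}" for i in range(1, n_bits + 1)]


def build_table(
    results: list[CompoundDockingResult],
    receptors: dict[str, Molecule],
    residue_list,
    nobb: bool = True,
    params: GeometryParams | None = None,
    score_cutoff: float | None = None,
) -> pd.DataFrame:
    """The per-compound analysis table: columns ``y, name, dg, V1..Vn``.

    Compounds appear in input order.  With ``score_cutoff`` poses above the
    cutoff are dropped before aggregation (the fraction denominator is then
    the retained pose count); a compound with no retained pose gets an
    all-zero descriptor row with ``dg`` from its best pre-filter score.
    Labels must be present on every compound; duplicate names raise.
    """
    residue_list = tuple(residue_list)
    n_bits = BITS_PER_RESIDUE * len(residue_list)
    names = [r.name for r in results]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate compound names: {sorted(dupes)}")
    rows = []
    for result in results:
        if result.label is None:
            raise ValueError(f"{result.name}: activity label missing")
        dg = compound_dg(result)
        working = result if score_cutoff is None else filter_poses_by_score(result, score_cutoff)
        if working.runs:
            fractions = compound_fractions(working, receptors, residue_list, nobb=nobb, params=params)
        else:
            logger.warning("%s: no pose at or below %.2f kcal/mol; all-zero descriptors",
                           result.name, score_cutoff)
            fractions = np.zeros(n_bits)
        rows.append([result.label, result.name, dg, *fractions])
    return pd.DataFrame(rows, columns=["y", "name", "dg", *descriptor_columns(n_bits)])


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the analysis table as plain CSV (header ``y,name,dg,V1,...``)."""
    table.to_csv(path, index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read an analysis table written by :func:`write_table` (or equivalent)."""
    table = pd.read_csv(path)
    required = {"y", "name", "dg"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)} plus V1..Vn")
    return table
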