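"""Stage-2 filtering and even-spacing selection of the final array content.

Stage 2 keeps candidates with broad accession support, exonic location and
a position on one of the chromosome-scale pseudomolecules. The final
fixed-size array is then filled by pinning pre-validated SNPs and choosing
the remainder on an ideal physical grid per chromosome, so that array
density tracks candidate density while spacing stays as even as the
candidate supply allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import InvalidConfigError
from .utils import round_half_up


class AnnotationGapError(ValueError):
    """A candidate reached Stage 2 without a genic classification."""


class ConsistencyError(ValueError):
    pass


@dataclass
class SelectionPlan:
    """Slot budget of the array: total bead slots and the pre-validated SNPs
    pinned into them; the remainder is filled by even spacing."""

    total_slots: int
    pinned: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.total_slots < 0:
            raise InvalidConfigError("total_slots must be >= 0")
        if len(self.pinned) > self.total_slots:
            raise InvalidConfigError(
                f"{len(self.pinned)} pinned SNPs exceed {self.total_slots} slots"
            )

    @property
    def n_pinned(self) -> int:
        return len(self.pinned)

    @property
    def available_slots(self) -> int:
        return self.total_slots - self.n_pinned

    def selection_ratio(self, n_candidates: int) -> float:
        """Stage-2 candidates per available slot, rounded to 2 dp."""
        if self.available_slots <= 0:
            raise InvalidConfigError("no available slots")
        return round_half_up(n_candidates / self.available_slots, 2)


@dataclass
class ArrayDesign:
    """Ordered manifest of the chosen SNPs."""

    manifest: pd.DataFrame  # sorted by (chrom, pos); unique positions

    def __post_init__(self) -> None:
        m = self.manifest
        if len(m) and m.duplicated(["chrom", "pos"]).any():
            raise InvalidConfigError("duplicate positions in design")
        self.manifest = m.sort_values(["chrom", "pos"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.manifest)

    @property
    def per_chromosome_counts(self) -> pd.Series:
        return self.manifest.groupby("chrom").size()

    def positions_by_chromosome(self) -> dict[str, np.ndarray]:
        return {
            c: g["pos"].to_numpy()
            for c, g in self.manifest.groupby("chrom", sort=True)
        }


def filter_stage2(
    candidates: pd.DataFrame,
    min_support: int = 5,
    require_exonic: bool = True,
    require_pseudomolecule: bool = True,
    counts_out: dict | None = None,
) -> pd.DataFrame:
    """Design-level filter: accession support >= ``min_support``, exonic
    location, and placement on a pseudomolecule, applied in that order.

    ``counts_out`` receives the number removed by each rule in application
    order, so a selection funnel can be reconstructed from the log.
    Candidates must already be screened for assay type, probe-tail
    duplication and design score.
    """
    counts = {} if counts_out is None else counts_out
    df = candidates
    n0 = len(df)
    keep = df["n_support"] >= min_support if n0 else pd.Series(dtype=bool)
    counts["support"] = int(n0 - keep.sum()) if n0 else 0
    df = df[keep] if n0 else df

    if require_exonic:
        if len(df) and ("genic_class" not in df.columns or df["genic_class"].isna().any()):
            raise AnnotationGapError("candidate without genic classification")
        before = len(df)
        df = df[df["genic_class"] == "exonic"] if before else df
        counts["exonic"] = before - len(df)
    if require_pseudomolecule:
        before = len(df)
        if before:
            if "on_pseudomolecule" not in df.columns:
                raise AnnotationGapError("candidate without pseudomolecule flag")
            df = df[df["on_pseudomolecule"].astype(bool)]
        counts["pseudomolecule"] = before - len(df)
    return df.reset_index(drop=True)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer slots proportionally to ``weights``."""
    if total <= 0 or weights.sum() == 0:
        return np.zeros(len(weights), dtype=int)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def _grid_targets(lo: int, hi: int, m: int) -> np.ndarray:
    if m == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, m)


def _assign_to_grid(positions: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Optimal order-preserving assignment: choose ``len(grid)`` of the
    sorted ``positions`` minimising the summed distance of the j-th chosen
    position to the j-th grid target (dynamic program, O(n*m)); ties resolve
    to the lexicographically smallest subset (lower positions win)."""
    p = np.sort(positions).astype(float)
    n, m = len(p), len(grid)
    if m == 0:
        return p[:0].astype(positions.dtype)
    # f[j, i]: minimal cost of serving grid targets j.. with candidates i..
    f = np.full((m + 1, n + 1), np.inf)
    f[m, :] = 0.0
    for j in range(m - 1, -1, -1):
        take = np.abs(p - grid[j]) + f[j + 1, 1:]
        # running min from the right implements the skip option
        f[j, :-1] = np.minimum.accumulate(
            np.minimum(take, np.inf)[::-1]
        )[::-1]
    chosen = []
    i = 0
    for j in range(m):
        while True:
            take = abs(p[i] - grid[j]) + f[j + 1, i + 1]
            if take <= f[j, i] + 1e-6:
                chosen.append(i)
                i += 1
                break
            i += 1
    return np.sort(positions)[chosen]


def _select_on_chromosome(
    positions: np.ndarray, pinned_pos: np.ndarray, n_slots: int
) -> np.ndarray:
    """Choose ``n_slots`` candidate positions on one chromosome.

    An ideal grid of ``n_slots + len(pinned)`` targets spans the union of
    candidate and pinned positions; each pinned SNP first consumes its
    nearest free grid point, then the remaining targets are served by the
    total-distance-minimising assignment of candidates
    (:func:`_assign_to_grid`).
    """
    positions = np.sort(positions)
    n_slots = min(n_slots, len(positions))
    if n_slots <= 0:
        return positions[:0]
    all_pos = np.concatenate([positions, pinned_pos])
    m = n_slots + len(pinned_pos)
    grid = _grid_targets(int(all_pos.min()), int(all_pos.max()), m)
    free = np.ones(m, dtype=bool)
    for p in np.sort(pinned_pos):
        d = np.abs(grid - p)
        d[~free] = np.inf
        free[int(np.argmin(d))] = False
    return _assign_to_grid(positions, grid[free])


def select_even_spacing(stage2: pd.DataFrame, plan: SelectionPlan) -> ArrayDesign:
    """Fill the array: pin pre-validated SNPs, apportion the remaining slots
    to chromosomes proportionally to their Stage-2 candidate counts
    (largest-remainder rounding), and pick grid-nearest candidates within
    each chromosome. Output size is ``min(total_slots, pinned + candidates)``.
    """
    pinned = plan.pinned.copy()
    if len(pinned):
        pinned = pinned.assign(pinned=True)
    stage2 = stage2.copy()
    if len(stage2) and len(pinned):
        # a candidate that is also pinned occupies only its pinned slot
        pk = set(zip(pinned["chrom"], pinned["pos"]))
        mask = [
            (c, p) not in pk for c, p in zip(stage2["chrom"], stage2["pos"])
        ]
        stage2 = stage2[mask]
    stage2["pinned"] = False

    chrom_counts = (
        stage2.groupby("chrom").size() if len(stage2) else pd.Series(dtype=int)
    )
    chroms = list(chrom_counts.index)
    alloc = _largest_remainder(
        chrom_counts.to_numpy(dtype=float),
        min(plan.available_slots, len(stage2)),
    )
    picked_frames = [pinned] if len(pinned) else []
    for chrom, n_slots in zip(chroms, alloc):
        cand = stage2[stage2["chrom"] == chrom]
        pin_pos = (
            pinned[pinned["chrom"] == chrom]["pos"].to_numpy()
            if len(pinned)
            else np.array([], dtype=int)
        )
        sel = _select_on_chromosome(
            cand["pos"].to_numpy(), pin_pos, int(n_slots)
        )
        picked_frames.append(cand[cand["pos"].isin(sel)])
    if not picked_frames:
        return ArrayDesign(stage2.iloc[0:0])
    manifest = pd.concat(picked_frames, ignore_index=True)
    if "pinned" in manifest.columns:
        manifest["pinned"] = manifest["pinned"].fillna(False).astype(bool)
    return ArrayDesign(manifest)


def apply_manufacturing_dropout(
    design: ArrayDesign,
    dropout_ids: list[str] | None = None,
    rate: float | None = None,
    seed: int | None = None,
) -> ArrayDesign:
    """Remove SNPs lost during array manufacturing, either an explicit id
    list or a random fraction (deterministic under ``seed``)."""
    m = design.manifest
    if dropout_ids is not None:
        unknown = set(dropout_ids) - set(m["id"])
        if unknown:
            raise ConsistencyError(
                f"{len(unknown)} dropout ids not in design (e.g. {sorted(unknown)[:3]})"
            )
        return ArrayDesign(m[~m["id"].isin(dropout_ids)].reset_index(drop=True))
    if rate is None:
        raise InvalidConfigError("specify dropout_ids or rate")
    if not 0.0 <= rate <= 1.0:
        raise InvalidConfigError("rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(m)) >= rate
    return ArrayDesign(m[keep].reset_index(drop=True))
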