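"""Family-reference read-depth CNV calling.

A transparent stand-in for full targeted-capture CNV pipelines, keeping
their central design: the copy-number reference is built *within the
family* from the healthy members, so proband-specific gains and losses
show up as log2 depth ratios against that reference.

Procedure
---------
1. Each subject's per-target depths are rescaled to a fixed mean of
   ``NORM_MEAN_DEPTH`` reads per target. This removes library-size
   differences and makes the log2 ratios exactly invariant to a global
   rescaling of all input depths (the pseudocount is applied on the common
   scale).
2. The reference is the per-target median across the normalized healthy
   members; per-target spread (median absolute deviation) is recorded and
   zero-median targets are masked.
3. log2 ratio per target: ``log2((proband + c) / (reference + c))`` with
   pseudocount ``c = 1`` read on the normalized scale.
4. Segmentation is greedy threshold-plus-merge: consecutive targets on the
   same side of the gain/loss threshold are merged; runs shorter than
   ``min_targets`` revert to neutral. A heterozygous loss sits near
   log2(1/2) = -1, a single-copy gain near log2(3/2) ~ +0.585.

Only autosomes are guaranteed; segments on X/Y are emitted but flagged,
since quartets mix sexes and no ploidy correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Common per-target mean depth after normalization (arbitrary fixed scale).
NORM_MEAN_DEPTH = 100.0

SEX_CHROMS = {"X", "Y"}

TARGET_COLUMNS = ["chrom", "start", "end", "depth"]


@dataclass(frozen=True)
class CnvSegment:
    subject: str
    chrom: str
    start: int
    end: int
    n_targets: int
    mean_log2_ratio: float
    call: str  # gain | loss | neutral

    @property
    def on_sex_chrom(self) -> bool:
        return self.chrom in SEX_CHROMS


class GridMismatchError(ValueError):
    """Raised when depth profiles do not share the same target grid."""


def read_depth_table(path: str | Path, subject: str | None = None) -> pd.DataFrame:
    """Read a tab-separated per-target depth table (chrom, start, end, depth)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing depth columns {missing}")
    df = canonicalize_targets(df)
    if subject is not None:
        df = df.assign(subject=subject)
    return df


def canonicalize_targets(df: pd.DataFrame) -> pd.DataFrame:
    """Sort targets by (chrom, start) and validate the grid invariants."""
    def chrom_rank(c: str) -> tuple[int, object]:
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    df = (
        df.assign(_rank=df["chrom"].map(chrom_rank))
        .sort_values(["_rank", "start"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    if (df["depth"] < 0).any():
        raise ValueError("negative depths in profile")
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (ends < starts).any():
            raise ValueError(f"chrom {chrom}: target end < start")
        if len(grp) > 1 and (starts[1:] <= ends[:-1]).any():
            raise ValueError(f"chrom {chrom}: overlapping targets")
    return df


def _check_same_grid(frames: Sequence[pd.DataFrame]) -> None:
    base = frames[0][["chrom", "start", "end"]].reset_index(drop=True)
    for other in frames[1:]:
        grid = other[["chrom", "start", "end"]].reset_index(drop=True)
        if len(grid) != len(base) or not grid.equals(base):
            merged = base.merge(grid, how="outer", indicator=True)
            first_bad = merged[merged["_merge"] != "both"].iloc[0]
            raise GridMismatchError(
                "target grids differ; first mismatch: "
                f"{first_bad['chrom']}:{first_bad['start']}-{first_bad['end']}"
            )


def _normalize(depths: np.ndarray) -> np.ndarray:
    mean = depths.mean()
    if mean == 0:
        raise ValueError("profile has zero total depth")
    return depths * (NORM_MEAN_DEPTH / mean)


def build_family_reference(profiles: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Per-target median reference from the healthy family members.

    Profiles must share an identical target grid. Each member is first
    rescaled to the common mean depth; the reference holds the per-target
    median (``ref_depth``), the median absolute deviation (``spread``), and
    a ``masked`` flag for zero-median targets.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one healthy-member profile")
    profiles = [canonicalize_targets(p) for p in profiles]
    _check_same_grid(profiles)
    matrix = np.vstack([_normalize(p["depth"].to_numpy(dtype=float)) for p in profiles])
    median = np.median(matrix, axis=0)
    spread = np.median(np.abs(matrix - median), axis=0)
    out = profiles[0][["chrom", "start", "end"]].copy()
    out["ref_depth"] = median
    out["spread"] = spread
    out["masked"] = median == 0
    return out


def log2_ratios(proband: pd.DataFrame, reference: pd.DataFrame,
                pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-target log2 copy ratios of a proband against the family reference.

    Masked reference targets are excluded; raises if nothing remains.
    """
    proband = canonicalize_targets(proband)
    _check_same_grid([reference, proband])
    keep = ~reference["masked"].to_numpy()
    if not keep.any():
        raise ValueError("all reference targets are masked")
    depth = _normalize(proband["depth"].to_numpy(dtype=float))
    ratio = np.log2(
        (depth[keep] + pseudocount)
        / (reference["ref_depth"].to_numpy()[keep] + pseudocount)
    )
    out = reference.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
    out["log2_ratio"] = ratio
    return out


def segment_and_call(
    ratios: pd.DataFrame,
    subject: str = "",
    min_targets: int = 3,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
) -> list[CnvSegment]:
    """Greedy merge of consecutive same-state targets into CNV segments.

    A target's state is gain if its ratio >= gain_threshold, loss if
    <= loss_threshold, else neutral. Consecutive targets in the same state
    on the same chromosome merge; gain/loss runs shorter than
    ``min_targets`` are demoted to neutral. All segments (including
    neutral) are returned in genome order.
    """
    if not (loss_threshold < 0 < gain_threshold):
        raise ValueError("thresholds must satisfy loss < 0 < gain")
    ratios = ratios.reset_index(drop=True)
    values = ratios["log2_ratio"].to_numpy()
    state = np.where(
        values >= gain_threshold, "gain", np.where(values <= loss_threshold, "loss", "neutral")
    )
    segments: list[CnvSegment] = []
    runs: list[tuple[int, int, str]] = []  # (start_idx, end_idx, state)
    i = 0
    chroms = ratios["chrom"].to_numpy()
    while i < len(ratios):
        j = i
        while (
            j + 1 < len(ratios)
            and state[j + 1] == state[i]
            and chroms[j + 1] == chroms[i]
        ):
            j += 1
        runs.append((i, j, state[i]))
        i = j + 1
    # demote short gain/loss runs, then re-merge adjacent neutrals
    demoted = [
        (a, b, "neutral" if s != "neutral" and b - a + 1 < min_targets else s)
        for a, b, s in runs
    ]
    merged: list[tuple[int, int, str]] = []
    for a, b, s in demoted:
        if merged and merged[-1][2] == s and chroms[merged[-1][1]] == chroms[a]:
            merged[-1] = (merged[-1][0], b, s)
        else:
            merged.append((a, b, s))
    for a, b, s in merged:
        segments.append(
            CnvSegment(
                subject=subject,
                chrom=str(chroms[a]),
                start=int(ratios["start"].iloc[a]),
                end=int(ratios["end"].iloc[b]),
                n_targets=b - a + 1,
                mean_log2_ratio=float(values[a : b + 1].mean()),
                call=s,
            )
        )
    return segments


def call_family_cnvs(
    proband_profile: pd.DataFrame,
    healthy_profiles: Sequence[pd.DataFrame],
    subject: str = "",
    min_targets: int = 3,
    gain_threshold: float = 0.3,
    loss_threshold: float = -0.3,
    pseudocount: float = 1.0,
) -> list[CnvSegment]:
    """Reference build + ratio + segmentation for one proband."""
    reference = build_family_reference(healthy_profiles)
    ratios = log2_ratios(proband_profile, reference, pseudocount=pseudocount)
    return segment_and_call(
        ratios,
        subject=subject,
        min_targets=min_targets,
        gain_threshold=gain_threshold,
        loss_threshold=loss_threshold,
    )


def segments_table(segments: Iterable[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [s.subject for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_targets": [s.n_targets for s in segments],
            "mean_log2_ratio": [round(s.mean_log2_ratio, 6) for s in segments],
            "call": [s.call for s in segments],
            "sex_chrom_flag": [s.on_sex_chrom for s in segments],
        }
    )
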