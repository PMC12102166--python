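"""Tumor mutational burden, kataegis detection, and telomere purity correction.

TMB is the count of somatic SNVs and indels falling in coding regions per
megabase of merged, non-overlapping coding sequence. Hypermutated
(kataegis) regions are local SNV clusters: at least ``min_snvs``
consecutive SNVs whose mean inter-mutational distance is below
``max_mean_imd`` bp. Telomere content measured on a bulk tumor sample is a
purity-weighted mixture of tumor and admixed-normal telomere content; the
exact de-mixing is

    telomere_corrected = (telomere_tumor - telomere_control * (1 - tcc)) / tcc
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GENCODE_V19_CODING_BP",
    "TelomereMeasurement",
    "merge_intervals",
    "merged_length",
    "tmb",
    "detect_hypermutated",
    "correct_telomere",
]

#: merged non-overlapping coding length of the Gencode v19 gene models,
#: used as the TMB denominator when no coding BED is supplied
GENCODE_V19_CODING_BP = 35_345_952


@dataclass
class TelomereMeasurement:
    """Telomere content of a tumor/control pair plus tumor purity."""

    telomere_tumor: float
    telomere_control: float
    tcc: float

    def __post_init__(self):
        if self.telomere_tumor < 0 or self.telomere_control < 0:
            raise ValueError("telomere contents must be >= 0")
        if not 0.0 < self.tcc <= 1.0:
            raise ValueError(f"tcc must be in (0, 1], got {self.tcc}")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals on one chromosome."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_length(intervals: Mapping[str, Iterable[tuple[int, int]]]) -> int:
    """Summed length of distinct non-overlapping intervals, per-chromosome union."""
    return sum(
        e - s for chrom_ivs in intervals.values() for s, e in merge_intervals(chrom_ivs)
    )


def _in_intervals(positions: np.ndarray, merged: list[tuple[int, int]]) -> np.ndarray:
    """Membership of 1-based positions in merged 0-based half-open intervals."""
    if not merged:
        return np.zeros(len(positions), dtype=bool)
    starts = np.array([s for s, _ in merged])
    ends = np.array([e for _, e in merged])
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    idx = np.searchsorted(starts, pos0, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pos0[ok] < ends[idx[ok]]
    return ok


def tmb(
    mutations: pd.DataFrame,
    coding_intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None,
    coding_length: int = GENCODE_V19_CODING_BP,
) -> float:
    """Mutations per megabase of coding sequence.

    With ``coding_intervals`` given, both the mutation count (SNVs and
    indels whose 1-based position lies in the merged union) and the
    denominator come from the BED; without it, all supplied mutations are
    assumed coding and divided by ``coding_length`` (Gencode v19 default).
    """
    if coding_intervals is not None:
        merged = {c: merge_intervals(iv) for c, iv in coding_intervals.items()}
        length = sum(e - s for ivs in merged.values() for s, e in ivs)
        if length == 0:
            raise ValueError("coding interval set is empty")
        n = 0
        for chrom, sub in mutations.groupby("chrom"):
            n += int(_in_intervals(sub["pos"].to_numpy(), merged.get(chrom, [])).sum())
    else:
        length = int(coding_length)
        if length <= 0:
            raise ValueError("coding_length must be positive")
        n = len(mutations)
    return n / (length / 1e6)


def detect_hypermutated(
    snvs: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    min_snvs: int = 6,
    max_mean_imd: float = 1000.0,
) -> pd.DataFrame:
    """Find local SNV clusters (kataegis) by inter-mutational distance.

    Scans each chromosome's sorted SNV positions for maximal runs of
    consecutive SNVs whose mean successive distance stays strictly below
    ``max_mean_imd``; runs of at least ``min_snvs`` SNVs are reported
    (start/end = first/last SNV position, 1-based inclusive). Runs never
    span chromosomes. ``genes`` (BED-like: chrom, start, end, name)
    annotates overlapping genes — those are the genes called hypermutated.
    """
    regions = []
    for chrom, sub in snvs.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy(dtype=np.int64))
        n = len(pos)
        i = 0
        while i < n:
            # grow the run while the running mean gap stays below the limit
            j = i
            gap_sum = 0
            while j + 1 < n:
                new_sum = gap_sum + (pos[j + 1] - pos[j])
                if new_sum / (j + 1 - i) >= max_mean_imd:
                    break
                gap_sum = new_sum
                j += 1
            count = j - i + 1
            if count >= min_snvs:
                regions.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[i]),
                        "end": int(pos[j]),
                        "n_snvs": count,
                        "mean_imd": gap_sum / (count - 1),
                    }
                )
                i = j + 1
            else:
                i += 1
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_snvs", "mean_imd"])
    if genes is not None:
        overlaps = []
        for row in out.itertuples(index=False):
            g = genes[
                (genes["chrom"] == row.chrom)
                & (genes["start"] < row.end)  # BED start 0-based < inclusive end
                & (genes["end"] >= row.start)  # half-open end >= 1-based start
            ]
            overlaps.append(",".join(g["name"].astype(str)))
        out["overlapping_genes"] = overlaps
    return out


def correct_telomere(measurement: TelomereMeasurement) -> tuple[float, bool]:
    """Purity-correct a tumor telomere content measurement.

    Returns ``(corrected, negative_flag)``; the corrected value
    ``(T - C*(1-tcc))/tcc`` can go negative when the control exceeds the
    tumor at low purity — it is reported as-is and flagged, never clipped.
    """
    t, c, tcc = measurement.telomere_tumor, measurement.telomere_control, measurement.tcc
    corrected = (t - c * (1.0 - tcc)) / tcc
    return corrected, corrected < 0
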