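"""Peak calling, trait comparison and track plotting for PPL scans.

A salient peak is a local PPL maximum of at least 0.20.  Around each peak
three nested intervals record how far the evidence extends: the contiguous
region over which the PPL stays ≥ 0.20 (narrow), ≥ 0.10 (intermediate) and
≥ 0.05 (broad).  Interval bounds snap to marker cM positions — two-point
scans have no between-marker values to interpolate.  Maxima whose broad
regions touch are merged to the higher peak, and peaks are separated only
where the track dips below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ppl import ScanResult

__all__ = ["Peak", "call_peaks", "compare_traits", "plot_tracks"]

NARROW, INTERMEDIATE, BROAD = 0.20, 0.10, 0.05


@dataclass
class Peak:
    chromosome: str
    peak_cm: float
    peak_ppl: float
    narrow: tuple[float, float]
    intermediate: tuple[float, float]
    broad: tuple[float, float]
    annotation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for inner, outer in ((self.narrow, self.intermediate), (self.intermediate, self.broad)):
            if not (outer[0] <= inner[0] and inner[1] <= outer[1]):
                raise ValueError("peak intervals must nest: narrow ⊆ intermediate ⊆ broad")


def _expand(ppl: np.ndarray, cm: np.ndarray, i: int, threshold: float) -> tuple[float, float]:
    lo = i
    while lo > 0 and ppl[lo - 1] >= threshold:
        lo -= 1
    hi = i
    while hi < len(ppl) - 1 and ppl[hi + 1] >= threshold:
        hi += 1
    return float(cm[lo]), float(cm[hi])


def call_peaks(
    scan: ScanResult, salience_min: float = NARROW, annotation: pd.DataFrame | None = None
) -> list[Peak]:
    """Salient PPL peaks with narrow/intermediate/broad width intervals.

    ``annotation``, if given, is a pass-through table with columns
    ``chrom, cm_lo, cm_hi`` plus arbitrary label columns (e.g. cytoband or
    bp positions); rows covering a peak position are attached verbatim.
    """
    if len(scan.frame) == 0:
        raise ValueError("empty scan")
    peaks: list[Peak] = []
    for chrom, grp in scan.frame.groupby("chrom", sort=False):
        cm = grp["cm"].to_numpy(float)
        ppl = grp["ppl"].to_numpy(float)
        n = len(ppl)
        candidates = [
            i
            for i in range(n)
            if ppl[i] >= salience_min
            and (i == 0 or ppl[i] >= ppl[i - 1])
            and (i == n - 1 or ppl[i] >= ppl[i + 1])
        ]
        # merge maxima sharing a broad region; keep the higher peak
        merged: list[int] = []
        for i in candidates:
            lo, hi = _expand(ppl, cm, i, BROAD)
            if merged:
                plo, phi = _expand(ppl, cm, merged[-1], BROAD)
                if lo <= phi and plo <= hi:  # overlapping broad support
                    if ppl[i] > ppl[merged[-1]]:
                        merged[-1] = i
                    continue
            merged.append(i)
        for i in merged:
            ann: dict = {}
            if annotation is not None:
                hit = annotation[
                    (annotation["chrom"].astype(str) == str(chrom))
                    & (annotation["cm_lo"] <= cm[i])
                    & (annotation["cm_hi"] >= cm[i])
                ]
                if len(hit):
                    ann = hit.iloc[0].to_dict()
            peaks.append(
                Peak(
                    chromosome=str(chrom),
                    peak_cm=float(cm[i]),
                    peak_ppl=float(ppl[i]),
                    narrow=_expand(ppl, cm, i, NARROW),
                    intermediate=_expand(ppl, cm, i, INTERMEDIATE),
                    broad=_expand(ppl, cm, i, BROAD),
                    annotation=ann,
                )
            )
    return peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    rows = []
    for p in peaks:
        rows.append(
            {
                "chrom": p.chromosome,
                "peak_cm": p.peak_cm,
                "peak_ppl": p.peak_ppl,
                "narrow_lo": p.narrow[0],
                "narrow_hi": p.narrow[1],
                "intermediate_lo": p.intermediate[0],
                "intermediate_hi": p.intermediate[1],
                "broad_lo": p.broad[0],
                "broad_hi": p.broad[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "peak_cm", "peak_ppl", "narrow_lo", "narrow_hi",
            "intermediate_lo", "intermediate_hi", "broad_lo", "broad_hi",
        ],
    )


def compare_traits(scan_asd: ScanResult, scan_bap: ScanResult) -> pd.DataFrame:
    """Position-by-position contrast of the ASD and ASD+BAP tracks.

    Returns one row per position with both PPLs, a categorical ``flag`` —
    ``ASD_SPECIFIC`` (ASD above the prior while ASD+BAP falls to or below
    it, i.e. including BAP cases flips the evidence), ``BAP_BOOSTED``
    (ASD+BAP exceeds ASD), ``SHARED`` (both above the prior), else
    ``NEITHER`` — and a ``direction`` column recording whether including
    BAP cases REDUCED, INCREASED or left EQUAL the signal.
    """
    key = ["chrom", "marker", "cm"]
    a, b = scan_asd.frame, scan_bap.frame
    if len(a) != len(b) or not (
        a[key].reset_index(drop=True) == b[key].reset_index(drop=True)
    ).all().all():
        raise ValueError("scan position grids do not match")
    pi = scan_asd.prior_pi
    asd = a["ppl"].to_numpy()
    bap = b["ppl"].to_numpy()
    flags = np.where(
        (asd > pi) & (bap <= pi),
        "ASD_SPECIFIC",
        np.where(
            bap > asd,
            "BAP_BOOSTED",
            np.where((asd > pi) & (bap > pi), "SHARED", "NEITHER"),
        ),
    )
    direction = np.where(bap < asd, "REDUCED", np.where(bap > asd, "INCREASED", "EQUAL"))
    out = a[key].reset_index(drop=True).copy()
    out["ppl_asd"] = asd
    out["ppl_asd_bap"] = bap
    out["flag"] = flags
    out["direction"] = direction
    return out


def plot_tracks(
    scans: dict[str, ScanResult],
    out_prefix: str,
    ylim: tuple[float, float] = (0.0, 1.0),
    fmt: str = "png",
) -> list[str]:
    """One PPL-vs-cM figure per chromosome, all scans overlaid.

    The y axis is fixed (default [0, 1]; use (0, 0.5) for a zoomed view)
    and the prior π is drawn as a horizontal reference line.  Returns the
    written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not scans:
        raise ValueError("need at least one scan to plot")
    first = next(iter(scans.values()))
    if len(first.frame) == 0:
        raise ValueError("empty scan")
    chroms = list(dict.fromkeys(first.frame["chrom"]))
    paths = []
    for chrom in chroms:
        fig, ax = plt.subplots(figsize=(7, 3))
        for label, scan in scans.items():
            grp = scan.frame[scan.frame["chrom"] == chrom]
            ax.plot(grp["cm"], grp["ppl"], marker=".", label=label)
        ax.axhline(first.prior_pi, color="grey", ls="--", lw=0.8, label="prior π")
        ax.set_xlabel("position (cM)")
        ax.set_ylabel("PPL")
        ax.set_ylim(*ylim)
        ax.set_title(f"chromosome {chrom}")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = f"{out_prefix}chr{chrom}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
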