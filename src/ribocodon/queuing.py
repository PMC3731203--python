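"""Ribosome queuing detection by metaplots around high-occupancy codons.

A stalled ribosome long-lived enough to impede traffic should accumulate a
trailing ribosome stacked directly behind it, visible as a secondary 5'-end
density peak approximately one footprint width (~28 nt) upstream of the slow
codon.  Candidates are codon instances (AAA/CAA by default) whose occupancy
rose at least 2-fold with adequate read support; the metaplot normalizes
each candidate's surrounding counts by its gene's mean per-nt density and
averages positions over the candidates whose host ORF covers them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import SITE_FIVEPRIME_OFFSET
from .footprints import PooledFiveprimeTrack
from .reference import OrfModel

log = logging.getLogger(__name__)


@dataclass
class QueuingConfig:
    codon_set: frozenset[str] = frozenset({"AAA", "CAA"})
    fold_min: float = 2.0
    reads_min: int = 32
    reads_min_mode: str = "each"  # or "combined"
    window: tuple[int, int] = (-45, 30)  # nt around the codon-in-A-site origin

    def __post_init__(self) -> None:
        if self.fold_min <= 1:
            raise ValueError("fold_min must exceed 1")
        if self.reads_min < 1:
            raise ValueError("reads_min must be >= 1")
        if self.reads_min_mode not in ("each", "combined"):
            raise ValueError("reads_min_mode must be 'each' or 'combined'")


def select_candidates(fold_changes: pd.DataFrame, config: QueuingConfig | None = None) -> pd.DataFrame:
    """Instances (rows of a matched fold-change table, A-site convention)
    passing the codon, fold and read-support thresholds."""
    cfg = config or QueuingConfig()
    df = fold_changes
    mask = df["codon"].isin(cfg.codon_set) & (df["fold_change"] >= cfg.fold_min)
    if cfg.reads_min_mode == "each":
        mask &= (df["reads_mut"] >= cfg.reads_min) & (df["reads_wt"] >= cfg.reads_min)
    else:
        mask &= (df["reads_mut"] + df["reads_wt"]) >= cfg.reads_min
    out = df[mask].copy()
    if len(out) == 0:
        log.warning("select_candidates: empty candidate set")
    return out


def queuing_metaplot(
    candidates: pd.DataFrame,
    track: PooledFiveprimeTrack,
    orfs: dict[str, OrfModel],
    config: QueuingConfig | None = None,
) -> pd.DataFrame:
    """Mean ORF-normalized 5'-end density around candidate codons.

    Window position 0 corresponds to 5' ends that place the candidate codon
    in the A site (origin = codon first nt - 15 in track coordinates).  Each
    candidate contributes counts divided by its ORF's mean per-nt density
    (shifted layer, ORF proper); each window position is divided by the
    number of candidates whose host ORF covers it, here the ORF interval
    [0, L) -- that convention makes a uniform-coverage gene exactly flat at 1.

    Returns a frame with columns position, mean_density, n_genes.
    """
    cfg = config or QueuingConfig()
    if len(candidates) == 0:
        raise ValueError("queuing metaplot needs a nonempty candidate set")
    lo, hi = cfg.window
    w = np.arange(lo, hi + 1)
    sums = np.zeros(len(w), dtype=float)
    denom = np.zeros(len(w), dtype=np.int64)
    dropped = 0
    for orf_id, codon_index in zip(candidates["orf_id"], candidates["codon_index"]):
        orf = orfs[orf_id]
        L = len(orf.coding_seq)
        arr = track.shifted_array(orf_id)
        orf_total = arr[track.upstream : track.upstream + L].sum()
        if orf_total == 0:
            dropped += 1
            continue
        mean_density = orf_total / L
        origin = 3 * int(codon_index) - SITE_FIVEPRIME_OFFSET["A"]
        tp = origin + w
        covered = (tp >= 0) & (tp < L)
        if not covered.any():
            dropped += 1
            continue
        vals = arr[np.clip(tp, -track.upstream, L + track.downstream - 1) + track.upstream]
        sums[covered] += vals[covered] / mean_density
        denom += covered
    if dropped:
        log.warning("queuing_metaplot: %d candidates dropped (no usable coverage)", dropped)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(denom > 0, sums / np.maximum(denom, 1), np.nan)
    return pd.DataFrame({"position": w, "mean_density": mean, "n_genes": denom})


def secondary_peak(metaplot: pd.DataFrame, search: tuple[int, int] = (-45, -1)) -> int:
    """Window position of the largest upstream density peak."""
    lo, hi = search
    sub = metaplot[(metaplot["position"] >= lo) & (metaplot["position"] <= hi)].dropna(
        subset=["mean_density"]
    )
    if len(sub) == 0:
        raise ValueError("no upstream positions with data")
    return int(sub.loc[sub["mean_density"].idxmax(), "position"])


def implied_ribosome_spacing(nt_per_ribosome: float = 164.0, nt_per_codon: int = 3) -> float:
    """Mean inter-ribosome spacing in codons implied by a mean ribosome
    density of one per ``nt_per_ribosome`` nt.

    At the cited yeast density of 1 per 164 nt this is ~54.7 codons: an
    elongation stall must exceed the translation time of that many codons
    before elongation, rather than initiation, limits protein output on the
    average transcript.
    """
    return nt_per_ribosome / nt_per_codon
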