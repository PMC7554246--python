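"""Comparative sequence statistics for positive vs negative fragment sets.

Four statistics characterise how ubiquitylated windows differ from
non-ubiquitylated ones:

* AAC — amino-acid composition, per-residue frequency A_r = N_r / N with
  N the pooled residue count (window length x fragment count, pad symbol
  included in the denominator).
* AAPC — adjacent-dipeptide composition D_{r,s} = N_{r,s} / N over the
  overlapping ordered residue pairs; pairs touching the pad symbol are
  excluded from numerator and denominator.
* PWM — residue-by-position occurrence counts with the central lysine
  column flagged.
* log-ratio — elementwise ln((pos + c) / (neg + c)) with Laplace
  pseudocount c, applied to pooled dipeptide frequencies (the P_{r,s}
  heatmap) and pooled positional counts (the M_PA heatmap).

A two-sample logo test flags (residue, position) cells whose occurrence
frequency differs significantly between the two sets (two-proportion
z test; optional Bonferroni correction across the tested cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .seq_data import AA_ALPHABET, ALPHABET, PAD_SYMBOL, encode_sequences

_N_AA = len(AA_ALPHABET)  # 20
_PAD_CODE = _N_AA  # X encodes as 20


def _sequences(fragments) -> list[str]:
    """Accept SiteFragment lists or raw equal-length strings."""
    return [f.sequence if hasattr(f, "sequence") else str(f) for f in fragments]


@dataclass
class AACVector:
    """Per-residue frequencies A_r over the 20 standard amino acids.

    ``counted_total`` is N = window x n_fragments; the pad symbol is part
    of N but is not reported as a residue, so the 20 frequencies sum to 1
    only for X-free input.
    """

    frequencies: np.ndarray  # (20,)
    counted_total: int
    residues: str = AA_ALPHABET

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=list(self.residues), name="frequency")


@dataclass
class AAPCMatrix:
    """Ordered adjacent-dipeptide frequencies D_{r,s} (row = first residue)."""

    frequencies: np.ndarray  # (20, 20)
    counted_pairs: int
    residues: str = AA_ALPHABET

    def as_frame(self) -> pd.DataFrame:
        idx = list(self.residues)
        return pd.DataFrame(self.frequencies, index=idx, columns=idx)


@dataclass
class PWMCounts:
    """Residue-by-position occurrence counts (21 rows: 20 residues + X)."""

    counts: np.ndarray  # (21, window) int
    n_fragments: int
    center_column: int  # 0-based column index of the central lysine

    @property
    def window(self) -> int:
        return self.counts.shape[1]

    def position_offsets(self) -> np.ndarray:
        """Offsets relative to the central lysine: -half .. 0 .. +half."""
        return np.arange(self.window) - self.center_column

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(ALPHABET), columns=self.position_offsets()
        )


@dataclass
class LogRatioMatrix:
    """Elementwise ln((pos + c)/(neg + c)); antisymmetric under set swap."""

    values: np.ndarray
    pseudocount: float


@dataclass
class LogoStats:
    """Two-sample logo: per (residue, position) enrichment significance.

    Arrays have shape (20, window); the centre column (always K by
    construction) is excluded from testing and carries NaN p-values.
    """

    freq_pos: np.ndarray
    freq_neg: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray  # bool
    enriched: np.ndarray  # bool; True where freq_pos > freq_neg
    alpha: float
    correction: str | None
    center_column: int
    residues: str = AA_ALPHABET

    def as_frame(self) -> pd.DataFrame:
        """Long-format table, one row per tested (residue, offset) cell."""
        n_res, window = self.z.shape
        offsets = np.arange(window) - self.center_column
        rows = []
        for i, res in enumerate(self.residues):
            for j in range(window):
                if j == self.center_column:
                    continue
                rows.append(
                    {
                        "residue": res,
                        "offset": offsets[j],
                        "freq_pos": self.freq_pos[i, j],
                        "freq_neg": self.freq_neg[i, j],
                        "z": self.z[i, j],
                        "p_value": self.p_value[i, j],
                        "direction": "enriched" if self.enriched[i, j] else "depleted",
                        "significant": bool(self.significant[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def compute_aac(fragments) -> AACVector:
    seqs = _sequences(fragments)
    if not seqs:
        raise ValueError("compute_aac: empty fragment list")
    codes = encode_sequences(seqs)
    n_total = codes.size
    counts = np.bincount(codes.ravel(), minlength=_N_AA + 1)[:_N_AA]
    return AACVector(counts.astype(float) / n_total, n_total)


def compute_aapc(fragments) -> AAPCMatrix:
    seqs = _sequences(fragments)
    if not seqs:
        raise ValueError("compute_aapc: empty fragment list")
    codes = encode_sequences(seqs)
    if codes.shape[1] < 2:
        raise ValueError("compute_aapc: fragments must have length >= 2")
    first = codes[:, :-1].ravel()
    second = codes[:, 1:].ravel()
    keep = (first != _PAD_CODE) & (second != _PAD_CODE)
    first, second = first[keep], second[keep]
    n_pairs = first.size
    counts = np.zeros((_N_AA, _N_AA), dtype=np.int64)
    np.add.at(counts, (first, second), 1)
    if n_pairs == 0:
        warnings.warn("compute_aapc: no countable pairs (all pairs touch X)")
        return AAPCMatrix(counts.astype(float), 0)
    return AAPCMatrix(counts.astype(float) / n_pairs, int(n_pairs))


def compute_pwm(fragments) -> PWMCounts:
    seqs = _sequences(fragments)
    if not seqs:
        raise ValueError("compute_pwm: empty fragment list")
    codes = encode_sequences(seqs)
    n, window = codes.shape
    counts = np.zeros((_N_AA + 1, window), dtype=np.int64)
    for j in range(window):
        counts[:, j] = np.bincount(codes[:, j], minlength=_N_AA + 1)
    return PWMCounts(counts, n, center_column=(window - 1) // 2)


def log_ratio(pos_table, neg_table, pseudocount: float = 1.0) -> LogRatioMatrix:
    """Elementwise ln((pos + pseudocount)/(neg + pseudocount)).

    Used both for the dipeptide-composition heatmap P_{r,s} (on pooled
    dipeptide frequencies) and for the positional heatmap M_PA (on pooled
    position counts).  The pseudocount keeps every cell finite.
    """
    pos = np.asarray(pos_table, dtype=float)
    neg = np.asarray(neg_table, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError(f"shape mismatch {pos.shape} vs {neg.shape}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return LogRatioMatrix(
        np.log((pos + pseudocount) / (neg + pseudocount)), pseudocount
    )


def pwm_log_ratio(
    pos_fragments, neg_fragments, pseudocount: float = 1.0
) -> LogRatioMatrix:
    """M_PA: positional log-ratio ln(sum M_pos / sum M_neg) over the 21 x window counts."""
    pos = compute_pwm(pos_fragments)
    neg = compute_pwm(neg_fragments)
    if pos.window != neg.window:
        raise ValueError("fragment sets have different window lengths")
    return log_ratio(pos.counts, neg.counts, pseudocount)


def aapc_log_ratio(
    pos_fragments, neg_fragments, pseudocount: float = 1.0
) -> LogRatioMatrix:
    """P_{r,s}: dipeptide-composition log-ratio between the two sets."""
    pos = compute_aapc(pos_fragments)
    neg = compute_aapc(neg_fragments)
    return log_ratio(pos.frequencies, neg.frequencies, pseudocount)


def two_sample_logo(
    pos_fragments,
    neg_fragments,
    alpha: float = 0.05,
    correction: str | None = None,
) -> LogoStats:
    """Two-proportion z test per (residue, position) cell between two sets.

    The centre column is excluded (it is K in every valid fragment).  With
    ``correction="bonferroni"`` the significance level is divided by the
    number of tested cells, 20 x (window - 1).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if correction not in (None, "bonferroni"):
        raise ValueError(f"unknown correction {correction!r}")
    pos = compute_pwm(pos_fragments)
    neg = compute_pwm(neg_fragments)
    if pos.window != neg.window:
        raise ValueError("fragment sets have different window lengths")
    n1, n2 = pos.n_fragments, neg.n_fragments
    x1 = pos.counts[:_N_AA].astype(float)
    x2 = neg.counts[:_N_AA].astype(float)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), 0.0)
    p_value = 2.0 * norm.sf(np.abs(z))

    center = pos.center_column
    n_tested = _N_AA * (pos.window - 1)
    alpha_eff = alpha / n_tested if correction == "bonferroni" else alpha
    significant = p_value <= alpha_eff
    significant[:, center] = False
    p_value = p_value.copy()
    p_value[:, center] = np.nan
    return LogoStats(
        freq_pos=p1,
        freq_neg=p2,
        z=z,
        p_value=p_value,
        significant=significant,
        enriched=p1 > p2,
        alpha=alpha,
        correction=correction,
        center_column=center,
    )


def write_feature_tables(
    pos_fragments,
    neg_fragments,
    out_dir,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    correction: str | None = None,
) -> dict[str, str]:
    """Compute all four statistics and write them as TSV tables under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    aac_pos = compute_aac(pos_fragments)
    aac_neg = compute_aac(neg_fragments)
    aac = pd.DataFrame(
        {
            "residue": list(AA_ALPHABET),
            "freq_pos": aac_pos.frequencies,
            "freq_neg": aac_neg.frequencies,
        }
    )
    paths["aac"] = os.path.join(out_dir, "aac.tsv")
    aac.to_csv(paths["aac"], sep="\t", index=False)

    aapc = aapc_log_ratio(pos_fragments, neg_fragments, pseudocount)
    idx = list(AA_ALPHABET)
    paths["aapc_logratio"] = os.path.join(out_dir, "aapc_logratio.tsv")
    pd.DataFrame(aapc.values, index=idx, columns=idx).to_csv(
        paths["aapc_logratio"], sep="\t"
    )

    mpa = pwm_log_ratio(pos_fragments, neg_fragments, pseudocount)
    pwm = compute_pwm(pos_fragments)
    paths["pwm_logratio"] = os.path.join(out_dir, "pwm_logratio.tsv")
    pd.DataFrame(
        mpa.values, index=list(ALPHABET), columns=pwm.position_offsets()
    ).to_csv(paths["pwm_logratio"], sep="\t")

    logo = two_sample_logo(pos_fragments, neg_fragments, alpha, correction)
    paths["logo_stats"] = os.path.join(out_dir, "logo_stats.tsv")
    logo.as_frame().to_csv(paths["logo_stats"], sep="\t", index=False)
    return paths
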