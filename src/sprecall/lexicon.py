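"""Reference word-frequency populations (lexicons).

A lexicon is the population of words a study list is drawn from, each word
carrying a usage frequency in occurrences per million. This module reads
lexicon tables in a few common dialects, fits the Zipfian (decaying
exponential) rank-frequency curve, partitions the frequency range into
equal-log-width bins, and compares an observed word pool against the
lexicon's bin distribution with an exact Dirichlet-multinomial Bayes factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "Lexicon",
    "ZipfFit",
    "BinPartition",
    "BayesFactorResult",
    "LexiconFormatError",
    "LexiconDataError",
    "DIALECTS",
    "load_lexicon",
    "fit_zipf",
    "partition_log_bins",
    "multinomial_bf",
]


class LexiconFormatError(ValueError):
    """The lexicon file does not expose the columns the dialect requires."""


class LexiconDataError(ValueError):
    """The lexicon file has rows that violate the data contract."""


@dataclass(frozen=True)
class Lexicon:
    """An immutable word-frequency population.

    Parameters
    ----------
    words : array of str
        Unique word tokens.
    freqs : array of float
        Frequency of use in occurrences per million; strictly positive.
    """

    words: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        words = np.asarray(self.words, dtype=object)
        freqs = np.asarray(self.freqs, dtype=float)
        if words.shape != freqs.shape or words.ndim != 1:
            raise ValueError("words and freqs must be 1-d arrays of equal length")
        if words.size < 1:
            raise LexiconDataError("a lexicon needs at least one entry")
        if not np.all(np.isfinite(freqs)) or np.any(freqs <= 0):
            bad = np.flatnonzero(~np.isfinite(freqs) | (freqs <= 0))[0]
            raise LexiconDataError(
                f"non-positive or non-finite frequency for word "
                f"{words[bad]!r} (row {bad})"
            )
        uniq, counts = np.unique(words.astype(str), return_counts=True)
        if np.any(counts > 1):
            dup = uniq[counts > 1][0]
            raise LexiconDataError(f"duplicate word in lexicon: {dup!r}")
        object.__setattr__(self, "words", words)
        object.__setattr__(self, "freqs", freqs)

    @property
    def total(self) -> int:
        """Number of words in the population (the T of the SP statistic)."""
        return int(self.freqs.size)

    @property
    def f_min(self) -> float:
        return float(self.freqs.min())

    @property
    def f_max(self) -> float:
        return float(self.freqs.max())

    def count_in_interval(self, low: float, high: float) -> int:
        """Count lexicon words with frequency in the closed interval [low, high]."""
        return int(np.count_nonzero((self.freqs >= low) & (self.freqs <= high)))

    def frequency_of(self, word: str) -> float:
        idx = np.flatnonzero(self.words.astype(str) == word)
        if idx.size == 0:
            raise KeyError(word)
        return float(self.freqs[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"word": self.words.astype(str), "freq_per_million": self.freqs})


#: Column-name maps for common lexicon file layouts. ``scale`` converts the
#: file's frequency unit to occurrences per million.
DIALECTS: dict[str, dict[str, object]] = {
    "generic": {"word": "word", "freq": "freq_per_million", "scale": 1.0},
    "lexique": {"word": "ortho", "freq": "freqlivres", "scale": 1.0},
    "subtlex": {"word": "Word", "freq": "SUBTLWF", "scale": 1.0},
}


def load_lexicon(
    path,
    dialect: str | dict = "generic",
    min_freq: float | None = None,
) -> Lexicon:
    """Read a lexicon from a delimited text file.

    TSV vs CSV is chosen by file extension (``.tsv``/``.txt`` use tabs).
    Rows with frequency below ``min_freq`` are dropped; duplicates and
    non-positive frequencies are errors.
    """
    mapping = DIALECTS[dialect] if isinstance(dialect, str) else dict(dialect)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    word_col, freq_col = mapping["word"], mapping["freq"]
    for col in (word_col, freq_col):
        if col not in df.columns:
            raise LexiconFormatError(
                f"column {col!r} not found in {path} (columns: {list(df.columns)})"
            )
    n_read = len(df)
    freqs = pd.to_numeric(df[freq_col], errors="coerce")
    if freqs.isna().any():
        row = int(freqs.index[freqs.isna()][0])
        raise LexiconDataError(f"non-numeric frequency in row {row} of {path}")
    freqs = freqs.to_numpy(dtype=float) * float(mapping.get("scale", 1.0))
    words = df[word_col].astype(str).to_numpy(dtype=object)
    if np.any(freqs <= 0):
        row = int(np.flatnonzero(freqs <= 0)[0])
        raise LexiconDataError(
            f"non-positive frequency for word {words[row]!r} (row {row}) in {path}"
        )
    if min_freq is not None:
        keep = freqs >= min_freq
        words, freqs = words[keep], freqs[keep]
    n_dropped = n_read - words.size
    if words.size == 0:
        raise LexiconDataError(f"no lexicon rows left after filtering {path}")
    logger.info("loaded lexicon %s: %d rows read, %d dropped", path, n_read, n_dropped)
    return Lexicon(words=words, freqs=freqs)


@dataclass(frozen=True)
class ZipfFit:
    """Decaying-exponential rank-frequency fit freq(r) = a * exp(-b * r)."""

    a: float
    b: float
    r_squared: float
    n_points: int
    scale: str = "raw"

    def predict(self, ranks: np.ndarray) -> np.ndarray:
        return self.a * np.exp(-self.b * np.asarray(ranks, dtype=float))


def _ranked_freqs(lexicon: Lexicon) -> np.ndarray:
    # rank 1 = most frequent; ties broken by word order so ranks stay 1..N
    order = np.lexsort((lexicon.words.astype(str), -lexicon.freqs))
    return lexicon.freqs[order]


def fit_zipf(lexicon: Lexicon, scale: str = "raw") -> ZipfFit:
    """Fit a decaying exponential to the rank-frequency curve.

    With ``scale="raw"`` (default), a and b are estimated by nonlinear least
    squares on raw frequencies and R^2 is 1 - SS_res/SS_tot on the raw scale.
    With ``scale="log"``, a linear fit of log(freq) on rank is used and R^2
    is computed on the log scale.
    """
    if lexicon.total < 3:
        raise ValueError("Zipf fit needs at least 3 words")
    f = _ranked_freqs(lexicon)
    if np.ptp(f) == 0:
        raise ValueError("degenerate input: all frequencies are equal")
    r = np.arange(1, f.size + 1, dtype=float)

    # log-linear regression supplies the (a, b) seed in both modes
    slope, intercept = np.polyfit(r, np.log(f), 1)
    a0, b0 = float(np.exp(intercept)), float(-slope)

    if scale == "log":
        fitted = intercept + slope * r
        resid = np.log(f) - fitted
        ss_tot = float(np.sum((np.log(f) - np.log(f).mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        if b0 <= 0 or a0 <= 0:
            raise RuntimeError("log-scale Zipf fit produced a non-decaying curve")
        return ZipfFit(a=a0, b=b0, r_squared=max(0.0, min(1.0, r2)),
                       n_points=f.size, scale="log")

    if scale != "raw":
        raise ValueError(f"unknown fit scale {scale!r}")
    try:
        popt, _ = curve_fit(
            lambda x, a, b: a * np.exp(-b * x),
            r, f, p0=[max(a0, f[0]), max(b0, 1e-12)], maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise RuntimeError(f"Zipf fit failed to converge: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    if a <= 0 or b <= 0:
        raise RuntimeError(
            f"Zipf fit produced non-positive parameters a={a:.4g}, b={b:.4g}"
        )
    resid = f - a * np.exp(-b * r)
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return ZipfFit(a=a, b=b, r_squared=max(0.0, min(1.0, r2)),
                   n_points=f.size, scale="raw")


@dataclass(frozen=True)
class BinPartition:
    """Equal-log10-width partition of a lexicon's frequency range.

    Bins are half-open on the right, except the last bin which is closed, so
    every word falls in exactly one bin.
    """

    k: int
    edges: np.ndarray  # k+1 log10-frequency boundaries
    counts: np.ndarray  # words per bin, sums to the lexicon total
    percentages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=int))
        total = self.counts.sum()
        pct = 100.0 * self.counts / total if total > 0 else np.zeros_like(self.counts, float)
        object.__setattr__(self, "percentages", pct)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def assign(self, freqs: np.ndarray) -> np.ndarray:
        """0-based bin index per frequency, same edge convention as counts."""
        logf = np.log10(np.asarray(freqs, dtype=float))
        idx = np.searchsorted(self.edges, logf, side="right") - 1
        return np.clip(idx, 0, self.k - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(self.k),
                "log10_low": self.edges[:-1],
                "log10_high": self.edges[1:],
                "count": self.counts,
                "percentage": self.percentages,
            }
        )


def partition_log_bins(lexicon: Lexicon, k: int = 10) -> BinPartition:
    """Partition [f_min, f_max] into ``k`` bins of equal log10 width."""
    if k < 1:
        raise ValueError("k must be >= 1")
    lo, hi = np.log10(lexicon.f_min), np.log10(lexicon.f_max)
    if lo == hi:
        # all mass at a single frequency: one token-width bin around it
        edges = np.array([lo - 0.5, lo + 0.5])
        return BinPartition(k=1, edges=edges, counts=np.array([lexicon.total]))
    edges = np.linspace(lo, hi, k + 1)
    counts, _ = np.histogram(np.log10(lexicon.freqs), bins=edges)
    return BinPartition(k=k, edges=edges, counts=counts)


@dataclass(frozen=True)
class BayesFactorResult:
    """BF10 for 'observed pool differs from the reference distribution'."""

    bf10: float
    posterior: float
    log_bf10: float
    infinite: bool = False


def multinomial_bf(observed, reference, alpha: float = 1.0) -> BayesFactorResult:
    """Exact multinomial Bayes factor: different vs same distribution.

    H0 holds the bin probabilities fixed at ``reference``; H1 places a
    symmetric Dirichlet(alpha) prior on them. BF10 is the ratio of the
    Dirichlet-multinomial marginal likelihood of ``observed`` to its
    multinomial likelihood under H0; the posterior probability of H1 under
    equal priors is BF10 / (1 + BF10).
    """
    x = np.asarray(observed, dtype=float)
    p = np.asarray(reference, dtype=float)
    if x.shape != p.shape or x.ndim != 1:
        raise ValueError("observed and reference must be 1-d and the same length")
    if np.any(x < 0) or not np.all(x == np.round(x)):
        raise ValueError("observed must be non-negative integer counts")
    n = x.sum()
    if n <= 0:
        raise ValueError("observed must contain at least one count")
    if abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
        raise ValueError("reference proportions must be non-negative and sum to 1")
    k = x.size
    if np.any((p == 0) & (x > 0)):
        return BayesFactorResult(bf10=np.inf, posterior=1.0, log_bf10=np.inf,
                                 infinite=True)
    # Dirichlet-multinomial marginal under symmetric Dirichlet(alpha)
    log_m1 = (
        gammaln(n + 1) - gammaln(x + 1).sum()
        + gammaln(k * alpha) - gammaln(n + k * alpha)
        + gammaln(x + alpha).sum() - k * gammaln(alpha)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        log_h0 = gammaln(n + 1) - gammaln(x + 1).sum() + np.where(x > 0, x * np.log(p, where=p > 0), 0.0).sum()
    log_bf = float(log_m1 - log_h0)
    bf = float(np.exp(log_bf))
    posterior = float(np.exp(log_bf - logsumexp([0.0, log_bf])))
    return BayesFactorResult(bf10=bf, posterior=posterior, log_bf10=log_bf)
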