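"""Order-dependent surprisal-proxy (SP) statistic for free-recall lists.

For each word of a presented list, SP compares how much of the reference
lexicon falls in a frequency interval "uncovered" by the word against how
much of the list falls there:

    SP = log10( sqrt(C / T) * W / (m / n) )

where the interval runs from the highest already-presented frequency not
exceeding the current word's frequency (or the lexicon minimum if no such
word exists) up to the current word's own frequency; W is its width, C the
number of lexicon words inside it (closed interval), T the lexicon size,
m the size of the word's tie group (an immediately consecutive run of list
words with the exact same frequency), and n the list length. Because the
lower bound depends on what has been presented so far, SP is a property of
a word *at its list position*, not of the word alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .lexicon import Lexicon

__all__ = [
    "StudyList",
    "SPConfig",
    "SPRecord",
    "sp_formula",
    "interval_lower_bound",
    "tie_groups",
    "compute_sp",
    "sp_table",
    "SurprisalProxy",
]

#: SP is defined in log base 10; the worked-example values (1.54, 2.79, ...)
#: only reproduce under base 10, so the base is not configurable.
LOG_BASE = 10


@dataclass(frozen=True)
class StudyList:
    """An ordered list of presented words with per-million frequencies."""

    words: tuple
    freqs: np.ndarray

    def __post_init__(self) -> None:
        words = tuple(str(w) for w in self.words)
        freqs = np.asarray(self.freqs, dtype=float)
        if len(words) != freqs.size or freqs.ndim != 1:
            raise ValueError("words and freqs must have equal length")
        if freqs.size == 0:
            raise ValueError("study list is empty")
        if np.any(freqs <= 0) or not np.all(np.isfinite(freqs)):
            raise ValueError("all list frequencies must be positive and finite")
        object.__setattr__(self, "words", words)
        object.__setattr__(self, "freqs", freqs)

    @property
    def n(self) -> int:
        return len(self.words)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lexicon: Lexicon | None = None) -> "StudyList":
        """Build from a long-format frame with columns position, word and
        optionally freq_per_million (looked up in the lexicon when absent)."""
        df = df.sort_values("position")
        pos = df["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(df) + 1)):
            raise ValueError("positions must be exactly 1..n")
        if "freq_per_million" in df.columns and df["freq_per_million"].notna().all():
            freqs = df["freq_per_million"].to_numpy(dtype=float)
        elif lexicon is not None:
            freqs = np.array([lexicon.frequency_of(w) for w in df["word"]])
        else:
            raise ValueError("no freq_per_million column and no lexicon to look up")
        return cls(words=tuple(df["word"]), freqs=freqs)


@dataclass(frozen=True)
class SPConfig:
    """Conventions for the SP computation.

    lower_bound_mode
        "lexicon_min": a word with no smaller presented predecessor takes the
        lexicon's minimum frequency as lower bound (the default convention).
        "first_word": it takes the first presented word's frequency instead
        (capped at its own frequency), the variant used to discuss SP
        dynamics in pure lists.
    n_override
        List length used in the m/n term when the scored items are a prefix
        of a longer list.
    clamp_low
        Permit list frequencies below the lexicon minimum by clamping the
        interval's lower bound to the word's own frequency (default: error).
    """

    lower_bound_mode: str = "lexicon_min"
    n_override: int | None = None
    clamp_low: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound_mode not in ("lexicon_min", "first_word"):
            raise ValueError(f"unknown lower_bound_mode {self.lower_bound_mode!r}")
        if self.n_override is not None and self.n_override < 1:
            raise ValueError("n_override must be >= 1")


@dataclass(frozen=True)
class SPRecord:
    """SP value for one list position, with the quantities behind it."""

    position: int
    word: str
    interval_low: float
    interval_high: float
    w_int: float
    count_lang: int  # C: lexicon words inside [interval_low, interval_high]
    total_lang: int  # T: lexicon size
    m: int  # tie-group size
    n: int  # list length used for PctList
    pct_list: float
    pct_language: float
    sp: float
    degenerate: bool = False


def sp_formula(count_lang: int, total_lang: int, w_int: float, m: int, n: int) -> float:
    """Evaluate SP = log10( sqrt(C/T) * W / (m/n) ).

    Returns -inf when C = 0 or W = 0 (nothing of the language, or a
    zero-width interval, is uncovered — no surprise is generated).
    """
    if total_lang < 1:
        raise ValueError("total_lang must be >= 1")
    if not 0 <= count_lang <= total_lang:
        raise ValueError("count_lang must be in [0, total_lang]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 1 <= m <= n:
        raise ValueError("m must be in [1, n]")
    if w_int < 0:
        raise ValueError("w_int must be non-negative")
    if count_lang == 0 or w_int == 0:
        return float("-inf")
    return float(
        np.log10(np.sqrt(count_lang / total_lang) * w_int / (m / n))
    )


def tie_groups(study_list: StudyList) -> list[range]:
    """Maximal runs of immediately consecutive equal-frequency positions.

    Returns 0-based index ranges; each position belongs to exactly one run
    and the run length is the m used for all its members. Grouping looks
    ahead over the full list — it is a property of the list, not of the
    presentation prefix.
    """
    f = study_list.freqs
    groups: list[range] = []
    start = 0
    for i in range(1, f.size):
        if f[i] != f[start]:
            groups.append(range(start, i))
            start = i
    groups.append(range(start, f.size))
    return groups


def interval_lower_bound(
    current_freq: float,
    presented_freqs,
    config: SPConfig,
    lexicon: Lexicon,
) -> float:
    """Lower bound of the SP interval for a word about to be scored.

    The bound is the highest already-presented frequency that does not
    exceed ``current_freq``; when none exists the fallback is the lexicon
    minimum (mode "lexicon_min") or the first presented word's frequency
    capped at ``current_freq`` (mode "first_word").
    """
    if current_freq <= 0:
        raise ValueError("current_freq must be positive")
    presented = np.asarray(list(presented_freqs), dtype=float)
    eligible = presented[presented <= current_freq]
    if eligible.size:
        return float(eligible.max())
    if config.lower_bound_mode == "first_word" and presented.size:
        return float(min(presented[0], current_freq))
    if config.lower_bound_mode == "first_word":
        # the first word has no predecessor: its own frequency, so W = 0
        return float(current_freq)
    return lexicon.f_min


def compute_sp(
    study_list: StudyList,
    lexicon: Lexicon,
    config: SPConfig = SPConfig(),
) -> list[SPRecord]:
    """SP for every position of a study list against a reference lexicon.

    Tie-group members share a single record's numeric content. C counts
    lexicon words over the closed interval [low, high]. Degenerate cases
    (W = 0 or C = 0) yield SP = -inf with the ``degenerate`` flag set.
    """
    n = config.n_override if config.n_override is not None else study_list.n
    if study_list.n > n:
        raise ValueError("n_override smaller than the actual list length")
    records: list[SPRecord] = [None] * study_list.n  # type: ignore[list-item]
    f = study_list.freqs
    for grp in tie_groups(study_list):
        start = grp.start
        freq = float(f[start])
        if freq < lexicon.f_min and not config.clamp_low:
            raise ValueError(
                f"list word {study_list.words[start]!r} has frequency {freq} "
                f"below the lexicon minimum {lexicon.f_min}; "
                "enable clamp_low to allow this"
            )
        low = interval_lower_bound(freq, f[:start], config, lexicon)
        low = min(low, freq)  # clamp covers freq < f_min under clamp_low
        high = freq
        w = high - low
        c = lexicon.count_in_interval(low, high)
        m = len(grp)
        sp = sp_formula(c, lexicon.total, w, m, n)
        degenerate = not np.isfinite(sp)
        if degenerate:
            warnings.warn(
                f"degenerate SP interval at position {start + 1} "
                f"({study_list.words[start]!r}): width={w}, count={c}",
                stacklevel=2,
            )
        proto = SPRecord(
            position=start + 1,
            word=study_list.words[start],
            interval_low=low,
            interval_high=high,
            w_int=w,
            count_lang=c,
            total_lang=lexicon.total,
            m=m,
            n=n,
            pct_list=m / n,
            pct_language=c / lexicon.total,
            sp=sp,
            degenerate=degenerate,
        )
        for i in grp:
            records[i] = replace(proto, position=i + 1, word=study_list.words[i])
    return records


def sp_table(records: list[SPRecord]) -> pd.DataFrame:
    """Tabulate SPRecords; -inf serialises as '-inf' when written to CSV."""
    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "word": [r.word for r in records],
            "interval_low": [r.interval_low for r in records],
            "interval_high": [r.interval_high for r in records],
            "w_int": [r.w_int for r in records],
            "count_lang": [r.count_lang for r in records],
            "total_lang": [r.total_lang for r in records],
            "m": [r.m for r in records],
            "n": [r.n for r in records],
            "pct_list": [r.pct_list for r in records],
            "pct_language": [r.pct_language for r in records],
            "sp": [r.sp for r in records],
            "degenerate": [r.degenerate for r in records],
        }
    )


class SurprisalProxy(BaseEstimator, TransformerMixin):
    """Transformer computing SP for study lists against a fitted lexicon.

    ``fit`` takes the reference :class:`~sprecall.lexicon.Lexicon`;
    ``transform`` takes a long-format DataFrame with columns ``position``,
    ``word``, ``freq_per_million`` and optionally ``subject_id``/``list_id``
    (each (subject, list) cell is scored as its own list) and returns the
    frame with SP columns appended.

    Parameters mirror :class:`SPConfig`.
    """

    def __init__(
        self,
        lower_bound_mode: str = "lexicon_min",
        n_override: int | None = None,
        clamp_low: bool = False,
    ):
        self.lower_bound_mode = lower_bound_mode
        self.n_override = n_override
        self.clamp_low = clamp_low

    def _config(self) -> SPConfig:
        return SPConfig(
            lower_bound_mode=self.lower_bound_mode,
            n_override=self.n_override,
            clamp_low=self.clamp_low,
        )

    def fit(self, X: Lexicon, y=None) -> "SurprisalProxy":
        if not isinstance(X, Lexicon):
            raise TypeError("SurprisalProxy.fit expects a Lexicon")
        self.lexicon_ = X
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("SurprisalProxy is not fitted")
        config = self._config()
        keys = [c for c in ("subject_id", "list_id") if c in X.columns]
        out = []
        grouped = X.groupby(keys, sort=False) if keys else [((), X)]
        for _, chunk in grouped:
            sl = StudyList.from_frame(chunk, self.lexicon_)
            recs = compute_sp(sl, self.lexicon_, config)
            tab = sp_table(recs)
            merged = chunk.merge(
                tab[["position", "sp", "interval_low", "interval_high",
                     "w_int", "count_lang", "m", "degenerate"]],
                on="position",
            )
            out.append(merged)
        return pd.concat(out, ignore_index=True)
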