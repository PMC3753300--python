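"""Novel-variant filtering and Ti/Tv mixture accounting.

High-throughput pooled resequencing yields a call set that mixes real
variants with recurrent sequencing artifacts. Two facts make the mixture
tractable:

* naturally occurring SNVs are transition-biased (Ti/Tv around 2.8-3.3),
  while a uniformly random error process hits 4 transition classes out of
  12, i.e. Ti/Tv = 0.5;
* artifacts tend to recur across the dataset, whereas genuinely novel
  variants are rare — so a "novel" variant seen many times is suspect.

The pipeline therefore (1) sets aside calls found in SNP databases as known,
(2) excludes novel calls whose occurrence exceeds a recurrence threshold
(default: observed at most 3 times), and (3) reports Ti/Tv per subset along
with the mixture estimate

    %TP = (Ti/Tv_obs - Ti/Tv_FP) / (Ti/Tv_TP - Ti/Tv_FP),

the estimated true-positive share of a call set given its observed ratio and
the pure-artifact and pure-true reference ratios. The estimate is a
diagnostic: the recurrence filter acts, the ratios verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .annotate import classify_substitution

DEFAULT_TITV_FP = 0.5
DEFAULT_TITV_TP_RANGE = (2.8, 3.3)
DEFAULT_MAX_OCCURRENCES = 3


class TpFraction(NamedTuple):
    value: float
    out_of_range: bool


def estimate_tp_fraction(
    titv_obs: float, titv_fp: float, titv_tp: float
) -> TpFraction:
    """True-positive share implied by an observed Ti/Tv ratio.

    Linear-mixture inversion between the pure-artifact ratio ``titv_fp`` and
    the pure-true ratio ``titv_tp``. The raw value is returned even outside
    [0, 1] (flagged), since an out-of-range estimate is itself informative:
    the observed ratio fell outside the assumed mixture endpoints.
    Strictly increasing in ``titv_obs``.
    """
    if titv_tp == titv_fp:
        raise ZeroDivisionError("titv_tp must differ from titv_fp")
    if titv_tp < titv_fp:
        raise ValueError("titv_tp must exceed titv_fp")
    value = (titv_obs - titv_fp) / (titv_tp - titv_fp)
    return TpFraction(value, out_of_range=not 0.0 <= value <= 1.0)


@dataclass
class TiTvSummary:
    """Transition/transversion tally with the mixture diagnostic.

    ``titv_obs`` is None when the set contains no transversions (the ratio
    is undefined; never reported as infinity). ``tp_fraction_range`` gives
    the %TP estimate at both endpoints of the assumed true-variant ratio
    range, clamped to [0, 1] with a flag when the raw value fell outside.
    """

    n_ti: int
    n_tv: int
    titv_fp: float = DEFAULT_TITV_FP
    titv_tp_range: tuple[float, float] = DEFAULT_TITV_TP_RANGE

    @property
    def titv_obs(self) -> float | None:
        if self.n_tv == 0:
            return None
        return self.n_ti / self.n_tv

    @property
    def tp_fraction_range(self) -> tuple[TpFraction, TpFraction] | None:
        obs = self.titv_obs
        if obs is None:
            return None
        out = []
        # higher assumed TP ratio -> lower %TP, so the range is (low, high)
        for tp in sorted(self.titv_tp_range, reverse=True):
            raw = estimate_tp_fraction(obs, self.titv_fp, tp)
            out.append(TpFraction(min(max(raw.value, 0.0), 1.0), raw.out_of_range))
        return out[0], out[1]

    def describe(self) -> str:
        obs = self.titv_obs
        obs_s = "undefined" if obs is None else f"{obs:.2f}"
        s = f"Ti {self.n_ti} / Tv {self.n_tv} (Ti/Tv {obs_s})"
        rng = self.tp_fraction_range
        if rng is not None:
            s += f"; %TP {100 * rng[0].value:.1f}-{100 * rng[1].value:.1f}"
        return s


def titv_ratio(
    calls: pd.DataFrame,
    titv_fp: float = DEFAULT_TITV_FP,
    titv_tp_range: tuple[float, float] = DEFAULT_TITV_TP_RANGE,
) -> TiTvSummary:
    """Tally transitions and transversions over a call table (ref/alt cols)."""
    classes = [
        classify_substitution(r, a)
        for r, a in zip(calls["ref"], calls["alt"])
    ]
    n_ti = sum(c == "Ti" for c in classes)
    return TiTvSummary(n_ti, len(classes) - n_ti, titv_fp, titv_tp_range)


def recurrence_filter(
    novel: pd.DataFrame,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
    occurrence_column: str = "occurrence_alleles",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split novel calls into retained (occurrence <= threshold) and excluded.

    The occurrence metric defaults to the total estimated minor-haplotype
    count across all pools; ``occurrence_column="occurrence_pools"`` switches
    to the number of pools carrying the variant.
    """
    if max_occurrences < 0:
        raise ValueError("max_occurrences must be non-negative")
    keep = novel[occurrence_column] <= max_occurrences
    return novel.loc[keep], novel.loc[~keep]


@dataclass
class FilterLedger:
    """Bookkeeping of the known/novel split and recurrence filter.

    The conservation identity n_total = n_known + n_novel_excluded +
    n_novel_retained holds by construction and is validated on creation.
    """

    n_total: int
    n_known: int
    n_novel_excluded: int
    n_novel_retained: int
    titv: dict[str, TiTvSummary] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_total != self.n_known + self.n_novel_excluded + self.n_novel_retained:
            raise ValueError(
                "conservation violated: "
                f"{self.n_total} != {self.n_known} + {self.n_novel_excluded} "
                f"+ {self.n_novel_retained}"
            )

    @classmethod
    def from_counts(
        cls, n_total: int, n_known: int, n_novel_excluded: int
    ) -> "FilterLedger":
        """Ledger from total/known/excluded counts; retained by conservation."""
        return cls(
            n_total,
            n_known,
            n_novel_excluded,
            n_total - n_known - n_novel_excluded,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.n_total),
            ("known", self.n_known),
            ("novel_excluded", self.n_novel_excluded),
            ("novel_retained", self.n_novel_retained),
        ]
        df = pd.DataFrame(rows, columns=["subset", "n"])
        df["n_ti"] = [self.titv.get(s).n_ti if s in self.titv else None for s, _ in rows]
        df["n_tv"] = [self.titv.get(s).n_tv if s in self.titv else None for s, _ in rows]
        df["titv_obs"] = [
            self.titv[s].titv_obs if s in self.titv else None for s, _ in rows
        ]
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def format_log(self) -> str:
        lines = [
            f"SNVs total: {self.n_total}",
            f"  known (in any database): {self.n_known}"
            + (f" [{self.titv['known'].describe()}]" if "known" in self.titv else ""),
            f"  novel, recurrence-excluded: {self.n_novel_excluded}"
            + (
                f" [{self.titv['novel_excluded'].describe()}]"
                if "novel_excluded" in self.titv
                else ""
            ),
            f"  novel, retained: {self.n_novel_retained}"
            + (
                f" [{self.titv['novel_retained'].describe()}]"
                if "novel_retained" in self.titv
                else ""
            ),
        ]
        return "\n".join(lines)


@dataclass
class QcResult:
    ledger: FilterLedger
    known: pd.DataFrame
    retained_novel: pd.DataFrame
    excluded_novel: pd.DataFrame

    @property
    def kept(self) -> pd.DataFrame:
        """Known plus retained-novel calls, the analysis set."""
        return pd.concat([self.known, self.retained_novel], ignore_index=True)


def apply_qc(
    annotated_calls: pd.DataFrame,
    max_occurrences: int = DEFAULT_MAX_OCCURRENCES,
    occurrence_column: str = "occurrence_alleles",
    titv_fp: float = DEFAULT_TITV_FP,
    titv_tp_range: tuple[float, float] = DEFAULT_TITV_TP_RANGE,
) -> QcResult:
    """Run the known/novel split and recurrence filter over annotated calls.

    ``annotated_calls`` must carry ``known`` (bool), ``ref``/``alt`` and the
    chosen occurrence column — i.e. a call table merged with its annotation.
    """
    known = annotated_calls.loc[annotated_calls["known"]]
    novel = annotated_calls.loc[~annotated_calls["known"]]
    retained, excluded = recurrence_filter(novel, max_occurrences, occurrence_column)
    titv = {}
    for name, subset in (
        ("total", annotated_calls),
        ("known", known),
        ("novel_prefilter", novel),
        ("novel_excluded", excluded),
        ("novel_retained", retained),
    ):
        if len(subset):
            titv[name] = titv_ratio(subset, titv_fp, titv_tp_range)
    ledger = FilterLedger(
        n_total=len(annotated_calls),
        n_known=len(known),
        n_novel_excluded=len(excluded),
        n_novel_retained=len(retained),
        titv=titv,
    )
    return QcResult(ledger, known, retained, excluded)
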