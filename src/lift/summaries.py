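"""Expectation calculator, funnel statistics, seed planning, phenotype stats.

The expectation calculator implements the halving law of recurrent
backcrossing: after g meioses from a donor whose genome is a fraction f
unadapted, an unselected offspring is expected to carry f x 2^-g of it.
The calculator takes the meiosis count explicitly — generation labels such
as pBC'4 are not converted to meiosis counts automatically, because label
conventions differ between breeding programs (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import ValidationError
from .haplotype_tracing import UnadaptedReport

COUNT_COLUMNS = [
    "crosses",
    "pollinated_flowers",
    "fruits",
    "seeds",
    "sown",
    "scab_eliminated",
    "pre_mas_losses",
    "mas_tested",
    "rgene_carriers",
    "selected_for_lift",
    "parents_next_gen",
]


def expected_unadapted_fraction(donor_fraction: float, n_meioses: int) -> float:
    """Expected unadapted genome percent after ``n_meioses`` halvings.

    ``donor_fraction`` is in percent. Rounded to one decimal on output:
    (50, 1) -> 25.0, (75, 5) -> 2.3, (50, 4) -> 3.1.
    """
    if donor_fraction < 0 or n_meioses < 0:
        raise ValidationError("donor_fraction and n_meioses must be non-negative")
    return round(donor_fraction * 2.0 ** (-n_meioses), 1)


def unadapted_generation_summary(
    reports: Sequence[UnadaptedReport],
    labels: Sequence[str],
    meioses_per_label: Optional[Mapping[str, int]] = None,
    donor_fraction_percent: Optional[float] = None,
) -> pd.DataFrame:
    """Per-generation mean/min/max traced percent, with expectation column.

    The expectation column requires an explicit meiosis count per label
    (never inferred from the labels) plus the donor's unadapted percent.
    """
    if len(reports) != len(labels):
        raise ValidationError("reports and labels must be parallel")
    df = pd.DataFrame(
        {
            "label": labels,
            "percent": [r.percent_of_diploid_genome for r in reports],
        }
    )
    out = (
        df.groupby("label", sort=False)["percent"]
        .agg(n="size", mean="mean", min="min", max="max")
        .reset_index()
    )
    if meioses_per_label is not None and donor_fraction_percent is not None:
        out["n_meioses"] = [meioses_per_label.get(l) for l in out["label"]]
        out["expected_percent"] = [
            expected_unadapted_fraction(donor_fraction_percent, g)
            if g is not None
            else float("nan")
            for g in out["n_meioses"]
        ]
    return out


# ---------------------------------------------------------------------------
# Breeding-funnel statistics
# ---------------------------------------------------------------------------


@dataclass
class CrossRecordTable:
    """Per-generation, per-location breeding-funnel counts.

    Rows are keyed by (location, generation); all counts are non-negative.
    Derived ratios are computed by :func:`funnel_statistics`, never stored.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("location", "generation", *COUNT_COLUMNS):
            if col not in self.frame.columns:
                raise ValidationError(f"cross-record table missing column {col!r}")
        if (self.frame[COUNT_COLUMNS] < 0).any().any():
            raise ValidationError("cross-record counts must be >= 0")

    @classmethod
    def from_csv(cls, path) -> "CrossRecordTable":
        return cls(pd.read_csv(path))

    @classmethod
    def fbE_fixture(cls) -> "CrossRecordTable":
        """The packaged funnel table for the Fb_E introgression series."""
        ref = resources.files("lift.data").joinpath("fbE_table2.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def column_totals(self) -> pd.Series:
        return self.frame[COUNT_COLUMNS].sum()


def _ratio(num: float, den: float, ndigits: int) -> float:
    """Ratio rounded to ndigits; undefined (NaN) on a zero denominator."""
    if den == 0:
        return float("nan")
    return round(num / den, ndigits)


def funnel_statistics(table: CrossRecordTable) -> pd.DataFrame:
    """Derived per-location funnel statistics.

    Per location: column totals; fruits per pollinated flower and seeds per
    fruit (pooled, 2 decimals); each location's share of the grand totals
    (1 decimal, percent); per-generation averages over the generations with
    a nonzero cross count at that location (1 decimal); and the R-gene
    carrier percentage both pooled and as the mean of per-generation
    percentages. Zero denominators give NaN (undefined), never zero.
    """
    df = table.frame
    grand = df[COUNT_COLUMNS].sum()
    rows = {}
    for loc, sub in df.groupby("location", sort=False):
        tot = sub[COUNT_COLUMNS].sum()
        active = sub[sub["crosses"] > 0]
        n_active = len(active)
        row: dict[str, float] = {f"{c}_total": int(tot[c]) for c in COUNT_COLUMNS}
        row["n_active_generations"] = n_active
        for c in COUNT_COLUMNS:
            row[f"{c}_avg"] = _ratio(tot[c], n_active, 1)
            row[f"{c}_share_pct"] = _ratio(100.0 * tot[c], grand[c], 1)
        row["fruits_per_flower"] = _ratio(tot["fruits"], tot["pollinated_flowers"], 2)
        row["seeds_per_fruit"] = _ratio(tot["seeds"], tot["fruits"], 1)
        row["carrier_pct_pooled"] = _ratio(
            100.0 * tot["rgene_carriers"], tot["mas_tested"], 1
        )
        gen_pcts = [
            100.0 * r / t
            for r, t in zip(active["rgene_carriers"], active["mas_tested"])
            if t > 0
        ]
        row["carrier_pct_gen_mean"] = (
            round(float(np.mean(gen_pcts)), 1) if gen_pcts else float("nan")
        )
        rows[loc] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Seed planning
# ---------------------------------------------------------------------------


def plan_seed_requirement(
    target_flowering_carriers: int,
    survival_rate: float,
    carrier_rate: float,
    flowering_rate: float,
) -> int:
    """Seeds needed so the expected number of flowering carriers hits target.

    ``survival_rate`` covers losses from sowing to MAS, ``carrier_rate`` is
    the Mendelian R-gene fraction (0.5 for a single heterozygous gene), and
    ``flowering_rate`` the fraction flowering early enough to use. With the
    study-scale rates (0.65, 0.5, 0.2) a target of 39 seedlings costs 600
    seeds.
    """
    for r in (survival_rate, carrier_rate, flowering_rate):
        if not 0.0 < r <= 1.0:
            raise ValidationError("rates must lie in (0, 1]")
    if target_flowering_carriers < 0:
        raise ValidationError("target must be non-negative")
    return math.ceil(
        target_flowering_carriers / (survival_rate * carrier_rate * flowering_rate)
    )


def expected_flowering_carriers(
    seeds: int, survival_rate: float, carrier_rate: float, flowering_rate: float
) -> float:
    """Inverse of :func:`plan_seed_requirement`."""
    for r in (survival_rate, carrier_rate, flowering_rate):
        if not 0.0 < r <= 1.0:
            raise ValidationError("rates must lie in (0, 1]")
    return seeds * survival_rate * carrier_rate * flowering_rate


# ---------------------------------------------------------------------------
# Phenotype statistics
# ---------------------------------------------------------------------------


def relative_lesion_length(
    lesion_cm: float,
    shoot_cm: float,
    control_lesion_cm: float,
    control_shoot_cm: float,
) -> float:
    """Percent lesion length relative to the susceptible control.

    (lesion/shoot) / (control lesion/control shoot) x 100; a zero control
    lesion makes the statistic undefined (NaN, with a warning).
    """
    if shoot_cm <= 0 or control_shoot_cm <= 0:
        raise ValidationError("shoot lengths must be positive")
    if control_lesion_cm == 0:
        warnings.warn("control lesion length is zero; ratio undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (lesion_cm / shoot_cm) / (control_lesion_cm / control_shoot_cm)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def anova_tukey_letters(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD and a compact letter display.

    Groups sharing any letter are not significantly different at ``alpha``.
    Letters follow the insert-and-absorb construction over the Tukey
    all-pairs decisions. Degenerate data (all values identical) yields a
    single shared letter.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    for g in names:
        if len(groups[g]) < 2:
            raise ValidationError(f"group {g!r} needs at least two values")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    pooled_var = np.mean([a.var(ddof=1) for a in arrays])
    if pooled_var == 0:
        means = [a.mean() for a in arrays]
        reject = {
            (names[i], names[j]): means[i] != means[j]
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
        f_stat, p_val = float("nan"), 1.0
        pairwise = pd.DataFrame(
            [
                {"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0,
                 "reject": rej}
                for (a, b), rej in reject.items()
            ]
        )
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(groups[g]) for g in names])
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=[c for c in tk.summary().data[0]]
        ).rename(columns={"p-adj": "p_adj"})
        reject = {
            (row["group1"], row["group2"]): bool(row["reject"])
            for _, row in pairwise.iterrows()
        }
    order = sorted(names, key=lambda g: -np.mean(groups[g]))
    letters = _compact_letter_display(order, reject)
    return AnovaTukeyResult(float(f_stat), float(p_val), letters, pairwise)


def _compact_letter_display(
    order: Sequence[str], reject: Mapping[tuple[str, str], bool]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``reject[(a, b)]`` is True when a and b differ significantly (either
    key order accepted). Returns group -> letter string; groups sharing a
    letter are not significantly different.
    """

    def sig(a: str, b: str) -> bool:
        return bool(reject.get((a, b), reject.get((b, a), False)))

    columns: list[set[str]] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if not sig(a, b):
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                for piece in (col - {b}, col - {a}):
                    if not any(piece <= other for other in columns):
                        columns.append(piece)
    columns = [c for c in columns if not any(c < o for o in columns if o is not c)]
    # stable letter order: by the highest-ranked group each column contains
    rank = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for k, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[k % len(alphabet)]
    return letters
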