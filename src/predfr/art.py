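"""Aligned-rank-transform (ART) two-factor ANOVA for count responses.

Consumption counts out of a handful of offered prey are heavily tied and
far from normal, so a parametric factorial ANOVA is inappropriate. The ART
procedure handles this nonparametrically while still testing main effects
and the interaction: for each effect, the response is *aligned* (stripped
of every other effect), mid-ranked, and a conventional two-way
fixed-effects ANOVA is run on the ranks — only the target effect's test is
interpreted from each aligned table.

Alignment for observation y in cell (i, j), using unweighted marginal
means of cell means (identical to plain means in the balanced case):

    effect A:    y - cell_ij + (Abar_i - grand)
    effect B:    y - cell_ij + (Bbar_j - grand)
    effect AxB:  y - cell_ij + (cell_ij - Abar_i - Bbar_j + grand)

The standard validity diagnostic — a plain ANOVA on the aligned (unranked)
responses must show F ~ 0 for every non-target effect, and the aligned
values must sum to ~0 — is computed for every fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EFFECTS = ("A", "B", "AxB")


@dataclass(frozen=True)
class FactorialObservation:
    """One response count with its two factor levels."""

    factor_A: str
    factor_B: str
    response: float

    def __post_init__(self) -> None:
        if self.response < 0:
            raise ValueError("response must be non-negative")


@dataclass
class EffectTest:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class ArtResult:
    """Per-effect ART ANOVA tests plus alignment diagnostics.

    ``diagnostics['aligned_sum_max']`` is the largest absolute sum of
    aligned responses across effects (should be ~0);
    ``diagnostics['stripped_F']`` maps each target effect to the plain-ANOVA
    F values of its *non-target* effects on the aligned, unranked response
    (all should be ~0).
    """

    effects: dict
    diagnostics: dict = field(default_factory=dict)

    def anova_table(self) -> pd.DataFrame:
        rows = {
            name: {
                "F": t.F,
                "df_num": t.df_num,
                "df_den": t.df_den,
                "p": t.p,
            }
            for name, t in self.effects.items()
        }
        return pd.DataFrame(rows).T[["F", "df_num", "df_den", "p"]]

    def summary(self) -> str:
        lines = ["Aligned rank transform ANOVA"]
        lines.append(self.anova_table().to_string(float_format="%.4g"))
        lines.append(
            "max |sum(aligned)| = %.3g" % self.diagnostics.get("aligned_sum_max", np.nan)
        )
        return "\n".join(lines)


class _Layout:
    """Factor levels, cell indexing and mean machinery for a two-way design."""

    def __init__(self, data):
        if isinstance(data, pd.DataFrame):
            a = data["factor_A"].astype(str).to_numpy()
            b = data["factor_B"].astype(str).to_numpy()
            y = data["response"].to_numpy(dtype=float)
        else:
            data = list(data)
            a = np.array([str(o.factor_A) for o in data])
            b = np.array([str(o.factor_B) for o in data])
            y = np.array([float(o.response) for o in data])
        self.y = y
        self.a_levels = sorted(set(a))
        self.b_levels = sorted(set(b))
        self.ai = np.array([self.a_levels.index(v) for v in a])
        self.bi = np.array([self.b_levels.index(v) for v in b])
        self.na, self.nb = len(self.a_levels), len(self.b_levels)
        self.n = len(y)
        self.counts = np.zeros((self.na, self.nb), dtype=int)
        np.add.at(self.counts, (self.ai, self.bi), 1)
        if np.any(self.counts == 0):
            i, j = np.argwhere(self.counts == 0)[0]
            raise ValueError(
                f"empty cell ({self.a_levels[i]}, {self.b_levels[j]}): "
                "every factor combination needs at least one observation"
            )
        if self.na < 2 or self.nb < 2:
            raise ValueError("both factors need at least two levels")

    @property
    def balanced(self) -> bool:
        return len(np.unique(self.counts)) == 1

    def cell_means(self, y=None) -> np.ndarray:
        y = self.y if y is None else y
        sums = np.zeros((self.na, self.nb))
        np.add.at(sums, (self.ai, self.bi), y)
        return sums / self.counts

    def effect_estimates(self, y=None):
        """(grand, A margin, B margin, cell means), unweighted over cells."""
        cm = self.cell_means(y)
        a_marg = cm.mean(axis=1)
        b_marg = cm.mean(axis=0)
        grand = cm.mean()
        return grand, a_marg, b_marg, cm


def _anova_on(layout: _Layout, y: np.ndarray) -> dict:
    """Two-way fixed-effects ANOVA of y on the layout's factors.

    Balanced designs use closed-form sums of squares; unbalanced designs
    use type-III partitioning via statsmodels with sum-to-zero contrasts.
    Zero residual *and* effect variance yields F = 0, p = 1 (degenerate
    convention — all-tied responses occur with all-zero treatments).
    """
    na, nb = layout.na, layout.nb
    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_e = layout.n - na * nb
    if df_e <= 0:
        raise ValueError("need more observations than cells")

    if layout.balanced:
        r = layout.counts[0, 0]
        grand, a_marg, b_marg, cm = layout.effect_estimates(y)
        ss_a = nb * r * float(np.sum((a_marg - grand) ** 2))
        ss_b = na * r * float(np.sum((b_marg - grand) ** 2))
        inter = cm - a_marg[:, None] - b_marg[None, :] + grand
        ss_ab = r * float(np.sum(inter**2))
        resid = y - cm[layout.ai, layout.bi]
        ss_e = float(np.sum(resid**2))
        out = {}
        ms_e = ss_e / df_e
        total_var = float(np.var(y))
        for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("AxB", ss_ab, df_ab)):
            if total_var <= 1e-12:
                F, p = 0.0, 1.0  # all responses tied after ranking
            elif ms_e <= 1e-12:
                F, p = (0.0, 1.0) if ss <= 1e-12 else (np.inf, 0.0)
            else:
                F = (ss / df) / ms_e
                p = float(stats.f.sf(F, df, df_e))
            out[name] = EffectTest(F=float(F), df_num=df, df_den=df_e, p=p)
        return out

    # unbalanced: type-III via statsmodels
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    frame = pd.DataFrame(
        {
            "y": y,
            "A": [layout.a_levels[i] for i in layout.ai],
            "B": [layout.b_levels[j] for j in layout.bi],
        }
    )
    fit = smf.ols("y ~ C(A, Sum) * C(B, Sum)", data=frame).fit()
    if fit.ssr <= 1e-12:
        return {
            name: EffectTest(F=0.0, df_num=df, df_den=df_e, p=1.0)
            for name, df in (("A", df_a), ("B", df_b), ("AxB", df_ab))
        }
    table = anova_lm(fit, typ=3)
    key_map = {
        "A": "C(A, Sum)",
        "B": "C(B, Sum)",
        "AxB": "C(A, Sum):C(B, Sum)",
    }
    out = {}
    for name, key in key_map.items():
        out[name] = EffectTest(
            F=float(table.loc[key, "F"]),
            df_num=int(table.loc[key, "df"]),
            df_den=int(table.loc["Residual", "df"]),
            p=float(table.loc[key, "PR(>F)"]),
        )
    return out


def align_responses(data, effect: str) -> np.ndarray:
    """Aligned responses for one target effect (one value per observation).

    After alignment the data carry (numerically) zero signal for every
    non-target effect; the target effect's estimate is retained.
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}, got {effect!r}")
    layout = data if isinstance(data, _Layout) else _Layout(data)
    grand, a_marg, b_marg, cm = layout.effect_estimates()
    resid = layout.y - cm[layout.ai, layout.bi]
    if effect == "A":
        est = a_marg[layout.ai] - grand
    elif effect == "B":
        est = b_marg[layout.bi] - grand
    else:
        est = (
            cm[layout.ai, layout.bi]
            - a_marg[layout.ai]
            - b_marg[layout.bi]
            + grand
        )
    return resid + est


class AlignedRankANOVA:
    """ART model for a two-factor layout; ``fit()`` returns an ArtResult.

    Accepts a list of :class:`FactorialObservation` or a DataFrame with
    columns ``factor_A``, ``factor_B``, ``response``. Ties receive
    mid-ranks. Requires every cell non-empty and more observations than
    cells.
    """

    def __init__(self, data):
        self.layout = _Layout(data)
        self._aligned: dict[str, np.ndarray] = {}
        self._ranked: dict[str, np.ndarray] = {}

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, factor_A: str, factor_B: str,
                       response: str) -> "AlignedRankANOVA":
        return cls(
            frame.rename(
                columns={factor_A: "factor_A", factor_B: "factor_B",
                         response: "response"}
            )[["factor_A", "factor_B", "response"]]
        )

    def aligned(self, effect: str) -> np.ndarray:
        if effect not in self._aligned:
            self._aligned[effect] = align_responses(self.layout, effect)
        return self._aligned[effect]

    def ranked(self, effect: str) -> np.ndarray:
        if effect not in self._ranked:
            self._ranked[effect] = stats.rankdata(self.aligned(effect))
        return self._ranked[effect]

    def fit(self) -> ArtResult:
        effects: dict[str, EffectTest] = {}
        stripped: dict[str, dict[str, float]] = {}
        max_sum = 0.0
        for effect in EFFECTS:
            aligned = self.aligned(effect)
            max_sum = max(max_sum, abs(float(np.sum(aligned))))
            table = _anova_on(self.layout, self.ranked(effect))
            effects[effect] = table[effect]
            plain = _anova_on(self.layout, aligned)
            stripped[effect] = {
                other: plain[other].F for other in EFFECTS if other != effect
            }
        return ArtResult(
            effects=effects,
            diagnostics={"aligned_sum_max": max_sum, "stripped_F": stripped},
        )

    # -- post hoc ------------------------------------------------------

    def posthoc(self, effect: str, adjustment: str = "tukey") -> pd.DataFrame:
        """Pairwise contrasts of estimated marginal means on ART ranks.

        Contrasts are computed on the response aligned-and-ranked for
        ``effect``, using the two-way rank ANOVA's residual mean square.
        ``adjustment`` is ``"tukey"`` (studentized range) or ``"holm"``.
        Returns a frame with one row per level pair: estimate (marginal
        mean difference on the rank scale), test statistic and adjusted p.
        """
        if adjustment not in ("tukey", "holm"):
            raise ValueError(f"unknown adjustment {adjustment!r}")
        if effect not in EFFECTS:
            raise ValueError(f"effect must be one of {EFFECTS}, got {effect!r}")
        layout = self.layout
        ranks = self.ranked(effect)
        table = _anova_on(layout, ranks)
        df_e = table[effect].df_den
        # residual MS of the full two-way model on these ranks
        cm = layout.cell_means(ranks)
        resid = ranks - cm[layout.ai, layout.bi]
        ms_e = float(np.sum(resid**2)) / df_e

        if effect == "A":
            labels = layout.a_levels
            means = cm.mean(axis=1)
            var_mean = (1.0 / layout.nb**2) * np.array(
                [np.sum(1.0 / layout.counts[i, :]) for i in range(layout.na)]
            )
        elif effect == "B":
            labels = layout.b_levels
            means = cm.mean(axis=0)
            var_mean = (1.0 / layout.na**2) * np.array(
                [np.sum(1.0 / layout.counts[:, j]) for j in range(layout.nb)]
            )
        else:
            labels = [
                f"{la}:{lb}" for la in layout.a_levels for lb in layout.b_levels
            ]
            means = cm.ravel()
            var_mean = 1.0 / layout.counts.ravel().astype(float)

        if len(labels) < 2:
            raise ValueError("effect needs at least two levels for contrasts")

        rows = []
        k = len(labels)
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                se = np.sqrt(ms_e * (var_mean[i] + var_mean[j]))
                if ms_e <= 1e-12:
                    stat, p_raw, p_tukey = 0.0, 1.0, 1.0
                elif adjustment == "tukey":
                    # studentized range statistic uses the SE of one mean
                    q = abs(diff) / (se / np.sqrt(2.0))
                    stat = q
                    p_tukey = float(stats.studentized_range.sf(q, k, df_e))
                    p_raw = None
                else:
                    t = diff / se
                    stat = t
                    p_raw = 2.0 * float(stats.t.sf(abs(t), df_e))
                    p_tukey = None
                rows.append(
                    {
                        "level_1": labels[i],
                        "level_2": labels[j],
                        "estimate": float(diff),
                        "statistic": float(stat),
                        "p_raw": p_raw,
                        "p_adj": p_tukey,
                    }
                )
        frame = pd.DataFrame(rows)
        if adjustment == "holm":
            raw = frame["p_raw"].to_numpy(dtype=float)
            frame["p_adj"] = multipletests(raw, method="holm")[1]
        else:
            frame = frame.drop(columns=["p_raw"])
        frame["p_adj"] = frame["p_adj"].clip(0.0, 1.0)
        frame.attrs["adjustment"] = adjustment
        frame.attrs["effect"] = effect
        return frame


# -- thin functional wrappers -----------------------------------------


def art_anova(data) -> ArtResult:
    """Fit the aligned-rank-transform two-way ANOVA."""
    return AlignedRankANOVA(data).fit()


def art_posthoc(data, effect: str, adjustment: str = "tukey") -> pd.DataFrame:
    """Pairwise post hoc contrasts on ART ranks for one effect."""
    return AlignedRankANOVA(data).posthoc(effect, adjustment=adjustment)
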