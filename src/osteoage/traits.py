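"""Ordinal trait observations: container, laterality collapse, encoding,
nearest-neighbour imputation and scoring concordance.

Observations are individuals × traits ordinal stage codes (0-based) with
missing values allowed. Preprocessing mirrors standard multifactorial
osteological practice: bilateral traits collapse to one column (left side
preferred, right as surrogate), and remaining gaps are filled from the
single most similar complete-enough individual (1-NN on Jaccard
similarity of one-hot encoded stages).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .schema import SchemaError, TraitSchema


class ValidationError(ValueError):
    """Raised when observations violate the trait schema."""


class ImputationError(ValueError):
    """Raised when 1-NN imputation cannot find a valid donor."""


class ObservationMatrix:
    """Individuals × traits ordinal stage matrix with optional ages.

    Stages are stored as a float DataFrame (NaN marks missing); the
    public accessors expose integer codes. Rows are individuals (index =
    id), columns are trait ids ordered as in ``schema``.
    """

    def __init__(
        self,
        stages: pd.DataFrame,
        schema: TraitSchema,
        ages: pd.Series | None = None,
    ):
        stages = stages.astype(float)
        missing_cols = [c for c in stages.columns if c not in schema]
        if missing_cols:
            raise ValidationError(f"columns not in schema: {missing_cols}")
        # validate stage codes against per-trait stage counts
        for tid in stages.columns:
            col = stages[tid]
            obs = col.dropna()
            if ((obs % 1) != 0).any():
                raise ValidationError(f"trait {tid!r}: non-integer stage code")
            n_stages = schema[tid].n_stages
            bad = obs[(obs < 0) | (obs >= n_stages)]
            if len(bad):
                raise ValidationError(
                    f"trait {tid!r}: stage codes outside 0..{n_stages - 1}: "
                    f"{sorted(bad.unique())}"
                )
        if ages is not None:
            ages = ages.astype(float).reindex(stages.index)
            if not np.isfinite(ages.to_numpy()).all():
                raise ValidationError("ages must be finite for all individuals")
            if (ages < 0).any():
                raise ValidationError("ages must be non-negative")
        self.stages = stages
        self.schema = schema
        self.ages = ages

    # ---- basic protocol ---------------------------------------------

    @property
    def individuals(self) -> list:
        return list(self.stages.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.stages.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.stages)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.stages.isna()

    @property
    def is_complete(self) -> bool:
        return not self.stages.isna().to_numpy().any()

    def subset_traits(self, trait_ids: list[str]) -> "ObservationMatrix":
        return ObservationMatrix(
            self.stages[list(trait_ids)], self.schema.subset(trait_ids), self.ages
        )

    def subset_individuals(self, index) -> "ObservationMatrix":
        ages = self.ages.loc[index] if self.ages is not None else None
        return ObservationMatrix(self.stages.loc[index], self.schema, ages)

    def copy(self) -> "ObservationMatrix":
        ages = self.ages.copy() if self.ages is not None else None
        return ObservationMatrix(self.stages.copy(), self.schema, ages)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationMatrix):
            return NotImplemented
        same_stages = self.stages.equals(other.stages)
        if self.ages is None or other.ages is None:
            return same_stages and (self.ages is None) == (other.ages is None)
        return same_stages and self.ages.equals(other.ages)

    # ---- CSV i/o -----------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        schema: TraitSchema,
        age_column: str = "age",
    ) -> "ObservationMatrix":
        """Read a trait CSV (first column = individual id, ``NA``/empty =
        missing, optional age column)."""
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
        ages = None
        if age_column in df.columns:
            ages = df.pop(age_column)
        return cls(df, schema, ages)

    def to_csv(self, path: str | Path, age_column: str = "age") -> None:
        df = self.stages.copy()
        if self.ages is not None:
            df[age_column] = self.ages
        df.to_csv(path, index_label="id")


# ---------------------------------------------------------------------
# laterality collapse
# ---------------------------------------------------------------------

def collapse_laterality(
    raw: pd.DataFrame, schema: TraitSchema, ages: pd.Series | None = None
) -> ObservationMatrix:
    """Collapse side-tagged observation columns to one column per trait.

    Bilateral traits appear in ``raw`` as ``<trait_id>.L`` and
    ``<trait_id>.R``; the left value is kept and the right is used as a
    surrogate only when the left is missing. Unilateral columns pass
    through unchanged.
    """
    out = {}
    seen: set[str] = set()
    for trait in schema:
        tid = trait.trait_id
        if trait.bilateral:
            tagged = [c for c in raw.columns if c in (f"{tid}.L", f"{tid}.R")]
            plain = [c for c in raw.columns if c == tid]
            if plain or len(tagged) > 2:
                raise SchemaError(
                    f"bilateral trait {tid!r}: expected at most two "
                    f"side-tagged columns, got {tagged + plain}"
                )
            left = raw.get(f"{tid}.L")
            right = raw.get(f"{tid}.R")
            if left is None and right is None:
                continue
            if left is None:
                col = right.copy()
            elif right is None:
                col = left.copy()
            else:
                col = left.where(left.notna(), right)
            out[tid] = col
            seen.update(tagged)
        elif tid in raw.columns:
            out[tid] = raw[tid]
            seen.add(tid)
    unknown = set(raw.columns) - seen
    if unknown:
        raise SchemaError(f"columns not matching any schema trait: {sorted(unknown)}")
    collapsed = pd.DataFrame(out, index=raw.index)
    return ObservationMatrix(collapsed, schema.subset(collapsed.columns), ages)


# ---------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class OneHotEncoding:
    """Binary indicator expansion of an ordinal stage matrix.

    ``indicators`` is n × K with one column per (trait, stage) pair;
    a missing stage yields an all-zero indicator group and a set bit in
    ``missing`` (n × m). ``columns`` maps indicator columns back to
    (trait_id, stage) pairs, making the encoding invertible.
    """

    indicators: np.ndarray
    columns: list[tuple[str, int]]
    missing: np.ndarray
    trait_ids: list[str]


def one_hot_encode(obs: ObservationMatrix) -> OneHotEncoding:
    cols: list[tuple[str, int]] = []
    blocks = []
    for tid in obs.trait_ids:
        n_stages = obs.schema[tid].n_stages
        codes = obs.stages[tid].to_numpy()
        block = np.zeros((len(codes), n_stages))
        seen = ~np.isnan(codes)
        block[seen, codes[seen].astype(int)] = 1.0
        blocks.append(block)
        cols.extend((tid, s) for s in range(n_stages))
    indicators = np.hstack(blocks) if blocks else np.zeros((obs.n_individuals, 0))
    return OneHotEncoding(
        indicators=indicators,
        columns=cols,
        missing=obs.missing_mask.to_numpy(),
        trait_ids=obs.trait_ids,
    )


def one_hot_decode(enc: OneHotEncoding, schema: TraitSchema,
                   index=None, ages: pd.Series | None = None) -> ObservationMatrix:
    """Invert :func:`one_hot_encode`."""
    n = enc.indicators.shape[0]
    data = {}
    start = 0
    for j, tid in enumerate(enc.trait_ids):
        n_stages = schema[tid].n_stages
        block = enc.indicators[:, start : start + n_stages]
        start += n_stages
        codes = block.argmax(axis=1).astype(float)
        codes[enc.missing[:, j]] = np.nan
        data[tid] = codes
    stages = pd.DataFrame(data, index=index if index is not None else range(n))
    return ObservationMatrix(stages, schema.subset(enc.trait_ids), ages)


# ---------------------------------------------------------------------
# 1-NN Jaccard imputation
# ---------------------------------------------------------------------

def impute_nn1_jaccard(
    obs: ObservationMatrix, donors: ObservationMatrix | None = None
) -> ObservationMatrix:
    """Fill every missing entry from a single nearest-neighbour donor.

    For each individual with missing traits, the donor is the individual
    (from ``donors``, default the matrix itself) maximising Jaccard
    similarity of one-hot indicators over traits observed in *both*;
    all the recipient's missing values are copied from that one donor.
    Ties break to the lowest donor position. Observed values are never
    altered, so the operation is idempotent.
    """
    if obs.is_complete:
        return obs.copy()
    pool = obs if donors is None else donors
    if list(pool.trait_ids) != list(obs.trait_ids):
        raise ImputationError("donor pool and recipients must share trait columns")

    enc_r = one_hot_encode(obs)
    enc_d = one_hot_encode(pool) if donors is not None else enc_r
    obs_seen = ~enc_r.missing  # recipients' observed traits
    don_seen = ~enc_d.missing

    # one-hot rows have exactly one "on" bit per observed trait, so the
    # Jaccard restricted to commonly observed traits reduces to
    # a / (2c - a): a = traits agreeing in stage, c = traits both observed
    agree = enc_r.indicators @ enc_d.indicators.T            # n_r × n_d
    both = obs_seen.astype(float) @ don_seen.astype(float).T
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(both > 0, agree / (2.0 * both - agree), -1.0)
    if donors is None:
        np.fill_diagonal(sim, -np.inf)

    filled = obs.stages.copy()
    donor_stages = pool.stages.to_numpy()

    for i in np.flatnonzero(enc_r.missing.any(axis=1)):
        miss = enc_r.missing[i]
        if not obs_seen[i].any():
            raise ImputationError(
                f"individual {obs.individuals[i]!r} has no observed traits; "
                "cannot match a donor"
            )
        # donor must supply every trait the recipient is missing
        eligible = don_seen[:, miss].all(axis=1)
        scores = np.where(eligible, sim[i], -np.inf)
        best_j = int(np.argmax(scores))
        if not np.isfinite(scores[best_j]) or scores[best_j] < 0:
            raise ImputationError(
                f"no donor observes all traits missing for individual "
                f"{obs.individuals[i]!r}"
            )
        cols = np.flatnonzero(miss)
        filled.iloc[i, cols] = donor_stages[best_j, cols]

    return ObservationMatrix(filled, obs.schema, obs.ages)


# ---------------------------------------------------------------------
# Kendall's W scoring concordance
# ---------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Per-trait Kendall's W between two scoring sessions.

    ``table`` has columns W, chi2, p; W is NaN where undefined (both
    sessions constant). ``mean_w`` averages the defined coefficients.
    """

    table: pd.DataFrame
    mean_w: float


def _kendalls_w_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Tie-corrected Kendall's W for two raters over n subjects."""
    n = len(a)
    m = 2
    ranks = np.column_stack(
        [stats.rankdata(a, method="average"), stats.rankdata(b, method="average")]
    )
    totals = ranks.sum(axis=1)
    s = float(np.sum((totals - totals.mean()) ** 2))
    ties = 0.0
    for col in ranks.T:
        _, counts = np.unique(col, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:
        return np.nan, np.nan, np.nan
    w = 12.0 * s / denom
    chi2 = m * (n - 1) * w
    p = float(stats.chi2.sf(chi2, df=n - 1))
    return w, chi2, p


def kendalls_w(session_a: pd.DataFrame, session_b: pd.DataFrame) -> ConcordanceReport:
    """Scoring concordance between two rating sessions of the same
    individuals on the same traits (0 = no agreement, 1 = perfect)."""
    if list(session_a.columns) != list(session_b.columns):
        raise ValidationError("sessions must rate the same traits")
    if list(session_a.index) != list(session_b.index):
        raise ValidationError("sessions must rate the same individuals")
    if len(session_a) < 3:
        raise ValidationError("Kendall's W requires at least 3 subjects")
    rows = {}
    for tid in session_a.columns:
        a = session_a[tid].to_numpy(dtype=float)
        b = session_b[tid].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValidationError(f"trait {tid!r}: missing ratings not allowed")
        rows[tid] = _kendalls_w_pair(a, b)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["W", "chi2", "p"])
    mean_w = float(table["W"].mean())
    return ConcordanceReport(table=table, mean_w=mean_w)
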