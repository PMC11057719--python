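"""Phenotypic scoring of premeiotic germline repair events.

Each F2 fly reports one germline repair event through its eye and body
color: red eyes mean the functional *white* gene was restored by HR
(whatever the body color); white eyes with a brown body mean the reporter
is intact — no DSB, precise end-joining, intersister HR, or NHEJ with
indels; white eyes with a yellow body mean the *y+* marker between the
repeats was lost, i.e. single-strand annealing (or a phenotypically
identical mitotic crossover).

The unit of analysis is the vial (one cross); group statistics are
unweighted means of per-vial percentages so each cross contributes equally
regardless of its progeny count, with the pooled-progeny proportion also
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOMES = ("HR", "NoDSB_NHEJ", "SSA")
EYE_COLORS = ("red", "white")
BODY_COLORS = ("brown", "yellow")
PARENT_SEXES = ("male", "female")

# Inverse of score_phenotype, used when rendering simulated progeny.
PHENOTYPE_BY_OUTCOME = {
    "HR": ("red", "brown"),
    "NoDSB_NHEJ": ("white", "brown"),
    "SSA": ("white", "yellow"),
}


@dataclass(frozen=True)
class ProgenyRecord:
    """One scored F2 fly."""

    eye_color: str
    body_color: str
    vial_id: str
    parent_sex: str

    def __post_init__(self) -> None:
        if self.eye_color not in EYE_COLORS:
            raise ValueError(f"eye_color must be one of {EYE_COLORS}")
        if self.body_color not in BODY_COLORS:
            raise ValueError(f"body_color must be one of {BODY_COLORS}")
        if self.parent_sex not in PARENT_SEXES:
            raise ValueError(f"parent_sex must be one of {PARENT_SEXES}")
        if not self.vial_id:
            raise ValueError("vial_id must be non-empty")


@dataclass(frozen=True)
class GermlineVial:
    """Outcome counts and percentages for one cross."""

    vial_id: str
    parent_sex: str
    counts: dict[str, int]
    total: int
    proportions: dict[str, float]  # percentages, sum to 100


def score_phenotype(eye_color: str, body_color: str) -> str:
    """Map an (eye, body) phenotype to its repair outcome.

    Red eyes score HR regardless of body color; a red-eyed yellow-bodied
    fly (a possible double event) is still scored HR but logged as an
    anomaly.
    """
    if eye_color not in EYE_COLORS:
        raise ValueError(f"eye_color must be one of {EYE_COLORS}")
    if body_color not in BODY_COLORS:
        raise ValueError(f"body_color must be one of {BODY_COLORS}")
    if eye_color == "red":
        if body_color == "yellow":
            logger.warning(
                "red-eyed yellow-bodied fly: possible HR + marker-loss double "
                "event; scored HR"
            )
        return "HR"
    return "NoDSB_NHEJ" if body_color == "brown" else "SSA"


def tally_vial(records: list[ProgenyRecord] | pd.DataFrame) -> GermlineVial:
    """Tally one vial's progeny into outcome counts and percentages."""
    if isinstance(records, pd.DataFrame):
        records = [
            ProgenyRecord(
                eye_color=r.eye_color,
                body_color=r.body_color,
                vial_id=str(r.vial_id),
                parent_sex=r.parent_sex,
            )
            for r in records.itertuples()
        ]
    if not records:
        raise ValueError("empty vial (unproductive cross); exclude upstream")
    vial_ids = {r.vial_id for r in records}
    sexes = {r.parent_sex for r in records}
    if len(vial_ids) != 1 or len(sexes) != 1:
        raise ValueError("tally_vial expects records from a single vial")
    counts = {o: 0 for o in OUTCOMES}
    for r in records:
        counts[score_phenotype(r.eye_color, r.body_color)] += 1
    total = sum(counts.values())
    return GermlineVial(
        vial_id=vial_ids.pop(),
        parent_sex=sexes.pop(),
        counts=counts,
        total=total,
        proportions={o: 100.0 * c / total for o, c in counts.items()},
    )


def tally_progeny_table(progeny: pd.DataFrame) -> list[GermlineVial]:
    """Tally every vial in a progeny table; empty vials cannot occur here."""
    vials = []
    for _, grp in progeny.groupby("vial_id", sort=True):
        vials.append(tally_vial(grp))
    return vials


def aggregate_germline(vials: list[GermlineVial]) -> pd.DataFrame:
    """Per-sex summary: mean and SEM of per-vial outcome percentages.

    The primary estimate is the unweighted mean over vials (each vial is one
    sample); the pooled-progeny percentage is reported alongside.  SEM is
    sd/sqrt(n) (ddof=1), NaN for a single vial.
    """
    if not vials:
        raise ValueError("no vials to aggregate")
    rows = []
    for sex in sorted({v.parent_sex for v in vials}):
        sub = [v for v in vials if v.parent_sex == sex]
        n = len(sub)
        row: dict[str, object] = {
            "parent_sex": sex,
            "n_vials": n,
            "total_progeny": sum(v.total for v in sub),
        }
        for o in OUTCOMES:
            vals = np.array([v.proportions[o] for v in sub], dtype=float)
            pooled = 100.0 * sum(v.counts[o] for v in sub) / row["total_progeny"]
            row[f"{o}_mean"] = float(vals.mean())
            row[f"{o}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
            )
            row[f"{o}_pooled"] = float(pooled)
        rows.append(row)
    return pd.DataFrame(rows)


def vials_to_frame(vials: list[GermlineVial]) -> pd.DataFrame:
    """Long per-vial table (one row per vial) of counts and percentages."""
    rows = []
    for v in vials:
        row: dict[str, object] = {
            "vial_id": v.vial_id,
            "parent_sex": v.parent_sex,
            "total": v.total,
        }
        for o in OUTCOMES:
            row[f"{o}_count"] = v.counts[o]
            row[f"{o}_pct"] = v.proportions[o]
        rows.append(row)
    return pd.DataFrame(rows)


def read_progeny_csv(path: str | Path) -> pd.DataFrame:
    """Read a progeny table (vial_id, parent_sex, eye_color, body_color)."""
    df = pd.read_csv(path, dtype=str)
    required = {"vial_id", "parent_sex", "eye_color", "body_color"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"progeny CSV missing columns: {sorted(missing)}")
    for col, allowed in (
        ("eye_color", EYE_COLORS),
        ("body_color", BODY_COLORS),
        ("parent_sex", PARENT_SEXES),
    ):
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValueError(f"invalid {col} value(s): {sorted(bad)}")
    return df
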