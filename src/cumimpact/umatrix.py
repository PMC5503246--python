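"""Uncertainty-matrix data model and semi-quantitative (SQ) scoring.

Following the Walker uncertainty typology, every source of uncertainty in
the assessment is classified by *location* (where in the modelling chain it
manifests: context, model, inputs, parameters, outcome), *level*
(statistical uncertainty, scenario uncertainty, recognized ignorance) and
*nature* (epistemic — reducible by more research — or variability —
inherent to the system). Locations are subdivided into sub-locations, the
concrete assumptions and decision nodes of the model.

The SQ scoring ranks sub-locations by uncertainty magnitude: each recorded
source scores the product of its level weight (statistical 1, scenario 2,
ignorance 3) and nature weight (epistemic 1, variability 3), giving the
six magnitude types {1, 2, 3, 3, 6, 9}; a sub-location's score is the sum
over its sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

LOCATIONS = ("context", "model", "inputs", "parameters", "outcome")
LEVELS = ("statistical", "scenario", "ignorance")
NATURES = ("epistemic", "variability")
PROVENANCES = ("M", "SE", "L")  # modelers, stakeholders/experts, literature


class MatrixError(ValueError):
    """The uncertainty matrix failed validation."""


@dataclass(frozen=True)
class UncertaintySource:
    sublocation_id: str
    level: str
    nature: str
    provenance: str = "M"
    description: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise MatrixError(f"unknown level {self.level!r}")
        if self.nature not in NATURES:
            raise MatrixError(f"unknown nature {self.nature!r}")
        if self.provenance not in PROVENANCES:
            raise MatrixError(f"unknown provenance {self.provenance!r}")


@dataclass(frozen=True)
class SubLocation:
    id: str
    location: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise MatrixError(f"unknown location {self.location!r}")


@dataclass
class UncertaintyMatrix:
    sublocations: list[SubLocation] = field(default_factory=list)
    sources: list[UncertaintySource] = field(default_factory=list)

    @classmethod
    def from_csv(cls, sublocations_csv: str | Path, sources_csv: str | Path) -> "UncertaintyMatrix":
        """Read sublocations.csv (id,location,name) and sources.csv
        (sublocation_id,level,nature,provenance,description)."""
        subs_df = pd.read_csv(sublocations_csv, comment="#")
        srcs_df = pd.read_csv(sources_csv, comment="#").fillna("")
        subs = [SubLocation(str(r.id), str(r.location), str(r.name)) for r in subs_df.itertuples()]
        srcs = [
            UncertaintySource(
                str(r.sublocation_id), str(r.level), str(r.nature),
                str(r.provenance) or "M", str(r.description),
            )
            for r in srcs_df.itertuples()
        ]
        return cls(subs, srcs)


@dataclass(frozen=True)
class MagnitudeWeights:
    """Level and nature weights, each in [1, 3]; products give the 6 magnitudes."""

    level_weight: tuple[tuple[str, float], ...] = (
        ("statistical", 1.0), ("scenario", 2.0), ("ignorance", 3.0),
    )
    nature_weight: tuple[tuple[str, float], ...] = (
        ("epistemic", 1.0), ("variability", 3.0),
    )

    @property
    def levels(self) -> dict[str, float]:
        return dict(self.level_weight)

    @property
    def natures(self) -> dict[str, float]:
        return dict(self.nature_weight)

    def magnitude(self, level: str, nature: str) -> float:
        return self.levels[level] * self.natures[nature]

    def magnitude_grid(self) -> list[float]:
        """All level x nature products (six values, with multiplicity)."""
        return [lw * nw for _, lw in self.level_weight for _, nw in self.nature_weight]


def validate_matrix(m: UncertaintyMatrix) -> dict[str, int]:
    """Referential-integrity check; returns location/sub-location/source counts."""
    ids = [s.id for s in m.sublocations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MatrixError(f"duplicate sub-location ids {dupes}")
    known = set(ids)
    for src in m.sources:
        if src.sublocation_id not in known:
            raise MatrixError(f"source references unknown sub-location {src.sublocation_id!r}")
    return {
        "n_locations": len({s.location for s in m.sublocations}),
        "n_sublocations": len(m.sublocations),
        "n_sources": len(m.sources),
    }


def sq_scores(
    m: UncertaintyMatrix, w: MagnitudeWeights = MagnitudeWeights()
) -> pd.DataFrame:
    """Per-sub-location uncertainty scores: sum of level*nature magnitudes."""
    validate_matrix(m)
    rows = []
    for sub in m.sublocations:
        score = sum(
            w.magnitude(src.level, src.nature)
            for src in m.sources
            if src.sublocation_id == sub.id
        )
        rows.append({"sublocation_id": sub.id, "location": sub.location,
                     "name": sub.name, "score": score})
    return pd.DataFrame(rows)


def sq_distributions(
    m: UncertaintyMatrix, w: MagnitudeWeights = MagnitudeWeights()
) -> dict[str, pd.Series]:
    """Percentage breakdowns of the total uncertainty score.

    Returns tables by location, by sub-location, by level and by nature;
    each sums to 100%.
    """
    scores = sq_scores(m, w)
    total = scores["score"].sum()
    if total == 0:
        logger.warning("sq_distributions: all scores are zero; percentages undefined")
        empty = scores.set_index("sublocation_id")["score"]
        return {"by_location": empty, "by_sublocation": empty,
                "by_level": empty, "by_nature": empty}
    by_loc = 100.0 * scores.groupby("location")["score"].sum() / total
    by_sub = 100.0 * scores.set_index("sublocation_id")["score"] / total
    src_df = pd.DataFrame(
        {
            "level": [s.level for s in m.sources],
            "nature": [s.nature for s in m.sources],
            "score": [w.magnitude(s.level, s.nature) for s in m.sources],
        }
    )
    by_level = 100.0 * src_df.groupby("level")["score"].sum() / total
    by_nature = 100.0 * src_df.groupby("nature")["score"].sum() / total
    return {"by_location": by_loc, "by_sublocation": by_sub,
            "by_level": by_level, "by_nature": by_nature}


def load_reference_matrix() -> UncertaintyMatrix:
    """The packaged Adriatic-Ionian case-study matrix fixture.

    A reconstruction of the published case study's structure (5 locations,
    17 sub-locations, 31 sources), assembled from the narrative account;
    an editable stand-in, not a verbatim copy of the survey tables.
    """
    pkg = resources.files("cumimpact") / "fixtures"
    with resources.as_file(pkg / "air_sublocations.csv") as subs, \
            resources.as_file(pkg / "air_sources.csv") as srcs:
        return UncertaintyMatrix.from_csv(subs, srcs)
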