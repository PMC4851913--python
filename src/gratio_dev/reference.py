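"""Published reference values: cohort demographics, hemispheric logarithmic
fits of the g-ratio index trajectory, and their extrapolated asymptotes.

These ship as a versioned YAML fixture inside the package so that
verification (:func:`gratio_dev.pipeline.verify_published_tables`) and the
synthetic-cohort calibration need no external input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

#: Age (days) at which fitted trajectories are extrapolated to estimate the
#: late-childhood plateau of the g-ratio index.
EXTRAPOLATION_AGE_DAYS = 10_000.0


@dataclass(frozen=True)
class PublishedFit:
    """One hemisphere's reported logarithmic fit g(age) = alpha*ln(age) + intercept."""

    region: str
    hemisphere: str  # "left" | "right"
    alpha: float
    intercept: float

    def predict(self, age_days: float) -> float:
        return self.alpha * math.log(age_days) + self.intercept


@lru_cache(maxsize=1)
def load_published_tables() -> dict:
    """Load the raw reference-table fixture as a dict."""
    text = resources.files("gratio_dev.data").joinpath("published_tables.yaml").read_text()
    return yaml.safe_load(text)


def published_fits() -> list[PublishedFit]:
    """All reported hemispheric fits, left then right within each region."""
    tables = load_published_tables()
    fits = []
    for region, entry in tables["trajectory_fits"].items():
        for hemi in ("left", "right"):
            fits.append(
                PublishedFit(
                    region=region,
                    hemisphere=hemi,
                    alpha=entry[hemi]["alpha"],
                    intercept=entry[hemi]["intercept"],
                )
            )
    return fits


def published_asymptote(region: str, hemisphere: str) -> float:
    """Reported asymptotic g-ratio index value for one region/hemisphere."""
    return float(load_published_tables()["asymptotes"][region][hemisphere])


def published_asymptote_values() -> list[float]:
    """All 20 reported asymptotic values (left and right of 10 regions)."""
    asym = load_published_tables()["asymptotes"]
    return [float(entry[h]) for entry in asym.values() for h in ("left", "right")]


def is_known_discrepant(region: str, hemisphere: str) -> bool:
    """True for cells whose reported asymptote does not match its own fit."""
    return any(
        d["region"] == region and d["hemisphere"] == hemisphere
        for d in load_published_tables().get("known_discrepant", [])
    )
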