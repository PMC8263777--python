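"""Per-drug SOC count profiles, the Z-score safety metric, and summaries.

For drug *j*, let N_i^j be the number of adverse events mapped to SOC *i*
(i = 1..27). The safety-concern metric standardizes each drug's own 27-count
profile:

    Z_i^j = (N_i^j - mu_j) / sigma_j,   mu_j = (sum_i N_i^j) / 27

with sigma_j the standard deviation of the 27 counts. By default sigma uses
the population divisor 27 (ddof=0): mu is defined over all 27 cells, no
Bessel correction is implied, and the choice yields exact invariants the
tests exploit — for every defined Z vector, sum(Z) = 0, sum(Z^2) = 27,
|Z| <= sqrt(26), and at most floor(27/4) = 6 cells can exceed 2. The sample
divisor (ddof=1) remains available for sensitivity analysis.

A SOC is called *significantly frequent* for a drug when Z > 2 (strictly);
the five safety bands follow the same half-open convention, so Z = 2.0 falls
in the "frequent" band, not the significant one. A drug whose 27 counts are
all equal (sigma = 0) has no defined Z; such drugs are reported separately
rather than forced to 0 or ±inf.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyProfileError
from .faers import DrugEventRecord
from .lexicon import DrugLexicon
from .vocab import N_SOC, SOCVocabulary


class Band(str, enum.Enum):
    SIGNIFICANTLY_FREQUENT = "significantly_frequent"  # Z > 2
    FREQUENT = "frequent"  # 1 < Z <= 2
    SLIGHTLY_FREQUENT = "slightly_frequent"  # 0 < Z <= 1
    LIKELY_INFREQUENT = "likely_infrequent"  # -1 < Z <= 0
    INFREQUENT = "infrequent"  # Z <= -1
    UNDEFINED = "undefined"  # sigma = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SIGNIFICANCE_THRESHOLD = 2.0


@dataclass(frozen=True)
class SOCProfile:
    """A drug's adverse-event counts over the 27 SOCs, in vocabulary order."""

    drug_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != N_SOC:
            raise ValueError(f"profile must have {N_SOC} counts")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class ZScoreRecord:
    drug_id: str
    soc_code: str
    z: Optional[float]  # None iff the profile has zero dispersion
    band: Band


def categorize(z: Optional[float]) -> Band:
    """Map a Z value to its safety band (half-open intervals, strict > 2)."""
    if z is None:
        return Band.UNDEFINED
    if z > 2:
        return Band.SIGNIFICANTLY_FREQUENT
    if z > 1:
        return Band.FREQUENT
    if z > 0:
        return Band.SLIGHTLY_FREQUENT
    if z > -1:
        return Band.LIKELY_INFREQUENT
    return Band.INFREQUENT


def aggregate_profiles(
    records: Iterable[DrugEventRecord],
    vocab: SOCVocabulary,
    stratum: Optional[str] = None,
) -> list[SOCProfile]:
    """Tally drug-event records into per-drug 27-SOC profiles.

    ``stratum`` selects the overall stream (None), or the ``"female"`` /
    ``"male"`` sub-streams; records without usable sex information belong to
    the overall stream only. One profile per drug with at least one record in
    the selected stream, sorted by drug_id.
    """
    tallies: dict[str, np.ndarray] = {}
    for rec in records:
        if stratum is not None and rec.sex_stratum != stratum:
            continue
        row = tallies.get(rec.drug_id)
        if row is None:
            row = tallies[rec.drug_id] = np.zeros(N_SOC, dtype=np.int64)
        row[vocab.index(rec.soc_code)] += 1
    return [
        SOCProfile(drug_id, tuple(int(c) for c in tallies[drug_id]))
        for drug_id in sorted(tallies)
    ]


def compute_zscores(
    profile: SOCProfile,
    vocab: SOCVocabulary,
    ddof: int = 0,
) -> list[ZScoreRecord]:
    """Compute the 27 Z-scores for one drug profile.

    ``ddof=0`` (default) divides the variance by 27; ``ddof=1`` by 26.
    Raises :class:`EmptyProfileError` on an all-zero profile; a profile with
    zero dispersion (all counts equal) yields 27 undefined records.
    """
    counts = np.asarray(profile.counts, dtype=float)
    if profile.total == 0:
        raise EmptyProfileError(f"drug {profile.drug_id!r} has no adverse events")
    mu = counts.sum() / N_SOC
    sigma = counts.std(ddof=ddof)
    out: list[ZScoreRecord] = []
    for i, code in enumerate(vocab.codes):
        if sigma == 0:
            out.append(ZScoreRecord(profile.drug_id, code, None, Band.UNDEFINED))
        else:
            z = float((counts[i] - mu) / sigma)
            out.append(ZScoreRecord(profile.drug_id, code, z, categorize(z)))
    return out


def significant_socs(zrecords: Iterable[ZScoreRecord]) -> set[str]:
    """SOC codes with Z strictly greater than 2."""
    return {
        r.soc_code
        for r in zrecords
        if r.z is not None and r.z > SIGNIFICANCE_THRESHOLD
    }


def z_matrix(
    profiles: Sequence[SOCProfile],
    vocab: SOCVocabulary,
    ddof: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug × SOC matrices of Z values and band labels.

    Rows are drug_ids (sorted), columns SOC abbreviations in vocabulary
    order. Undefined cells hold NaN in the Z matrix and "undefined" in the
    band matrix.
    """
    index = [p.drug_id for p in profiles]
    zs = np.full((len(profiles), N_SOC), np.nan)
    bands = np.empty((len(profiles), N_SOC), dtype=object)
    for r, profile in enumerate(profiles):
        for c, rec in enumerate(compute_zscores(profile, vocab, ddof)):
            if rec.z is not None:
                zs[r, c] = rec.z
            bands[r, c] = rec.band.value
    cols = list(vocab.abbreviations)
    return (
        pd.DataFrame(zs, index=index, columns=cols),
        pd.DataFrame(bands, index=index, columns=cols),
    )


def long_table(
    profiles: Sequence[SOCProfile],
    vocab: SOCVocabulary,
    ddof: int = 0,
    stratum: str = "overall",
) -> pd.DataFrame:
    """Long-format (drug, soc, count, z, band, stratum) table."""
    rows = []
    for profile in profiles:
        zrecs = compute_zscores(profile, vocab, ddof)
        for count, rec in zip(profile.counts, zrecs):
            rows.append(
                {
                    "drug_id": profile.drug_id,
                    "soc_code": rec.soc_code,
                    "count": count,
                    "z": rec.z,
                    "band": rec.band.value,
                    "stratum": stratum,
                }
            )
    return pd.DataFrame(
        rows, columns=["drug_id", "soc_code", "count", "z", "band", "stratum"]
    )


def atc_class_summary(
    profiles: Sequence[SOCProfile],
    lexicon: DrugLexicon,
    vocab: SOCVocabulary,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-ATC-class totals and averages of events and significant SOCs.

    Drugs without ATC codes are excluded. A drug with codes in several
    first-letter classes contributes its full totals to each distinct class
    (duplicate letters within one drug collapse to a single membership).
    """
    rows: dict[str, dict] = {}
    for profile in profiles:
        entry = lexicon.entries.get(profile.drug_id)
        if entry is None or not entry.atc_codes:
            continue
        n_sig = len(significant_socs(compute_zscores(profile, vocab, ddof)))
        for cls in sorted(entry.atc_classes()):
            agg = rows.setdefault(
                cls, {"n_drugs": 0, "total_events": 0, "total_significant_socs": 0}
            )
            agg["n_drugs"] += 1
            agg["total_events"] += profile.total
            agg["total_significant_socs"] += n_sig
    out = []
    for cls in sorted(rows):
        agg = rows[cls]
        out.append(
            {
                "atc_class": cls,
                "n_drugs": agg["n_drugs"],
                "total_events": agg["total_events"],
                "mean_events_per_drug": agg["total_events"] / agg["n_drugs"],
                "total_significant_socs": agg["total_significant_socs"],
                "mean_significant_socs": agg["total_significant_socs"] / agg["n_drugs"],
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "atc_class",
            "n_drugs",
            "total_events",
            "mean_events_per_drug",
            "total_significant_socs",
            "mean_significant_socs",
        ],
    )
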