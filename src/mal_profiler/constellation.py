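"""Lesion-constellation classification and cohort-level tabulation.

A patient's acute lesion burden is recorded as a lesion count per vascular
territory. "Multiple acute lesions" (MAL) means more than one discrete
acute lesion, regardless of whether the lesions share a territory: a
patient with three lesions inside the left MCA territory is a MAL patient
just like a patient with one MCA and one cerebellar lesion. Constellation
categories additionally distinguish, for multi-territory patients, whether
each involved territory hosts a single lesion or multiple lesions.

Derived flags:

* ``bilateral`` — lesions on both the left and the right side among the
  lateralized territories (ACA/MCA/PCA/cerebellum); the midline brainstem
  never counts toward bilaterality.
* ``supra_and_infra`` — lesions in both the supratentorial (ACA/MCA/PCA)
  and the infratentorial (cerebellum/brainstem) compartment.
* ``ant_and_post`` — lesions in both the anterior (ACA/MCA) and posterior
  (PCA/cerebellum/brainstem) circulation; equivalent to
  ``circulation == "both"``.

Note that neither flag implies the other: an MCA + PCA patient is
anterior + posterior but purely supratentorial, while a PCA + cerebellum
patient spans both compartments within the posterior circulation alone.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from mal_profiler.errors import EmptyInputError, ValidationError
from mal_profiler.territories import COUNT_COLUMNS, TERRITORY_ORDER, Territory

SINGLE_IN_ONE = "single-in-one-territory"
MULTIPLE_IN_ONE = "multiple-in-one-territory"
TWO_SINGLES = "two-singles-in-two-territories"
SINGLE_PLUS_MULTIPLE = "single+multiple-in-two-territories"

#: Columns appended to a cohort frame by :func:`label_cohort`.
LABEL_COLUMNS = (
    "n_lesions",
    "n_territories",
    "mal",
    "category",
    "bilateral",
    "supra_and_infra",
    "ant_and_post",
    "circulation",
)


@dataclass(frozen=True)
class ConstellationLabel:
    """Derived lesion-topology category and anatomical flags for one patient."""

    n_lesions: int
    n_territories: int
    mal: bool
    category: str
    bilateral: bool
    supra_and_infra: bool
    ant_and_post: bool
    circulation: str  # anterior | posterior | both

    #: per-territory status multiset, e.g. ("single", "multiple"), sorted
    statuses: tuple[str, ...] = ()


def _normalize_counts(counts: Mapping) -> dict[Territory, int]:
    """Accept Territory keys, territory codes ('mca_l') or column names ('n_mca_l')."""
    out: dict[Territory, int] = {}
    by_code = {t.value: t for t in Territory}
    by_col = {t.column: t for t in Territory}
    for key, value in counts.items():
        if isinstance(key, Territory):
            terr = key
        elif key in by_code:
            terr = by_code[key]
        elif key in by_col:
            terr = by_col[key]
        else:
            raise ValidationError(f"unknown territory key: {key!r}")
        count = int(value)
        if count < 0:
            raise ValidationError(f"negative lesion count for {terr.value}: {count}")
        out[terr] = count
    return out


def category_label(statuses: Sequence[str]) -> str:
    """Human-readable constellation category for a per-territory status multiset.

    ``statuses`` holds one entry ("single" or "multiple") per involved
    territory. The common one- and two-territory patterns get the names
    used in cohort reports; rarer patterns get a systematic name.
    """
    k = len(statuses)
    n_single = sum(1 for s in statuses if s == "single")
    n_multiple = k - n_single
    if k == 1:
        return SINGLE_IN_ONE if statuses[0] == "single" else MULTIPLE_IN_ONE
    if k == 2 and n_single == 2:
        return TWO_SINGLES
    if k == 2 and n_single == 1:
        return SINGLE_PLUS_MULTIPLE
    return f"{n_single}-single+{n_multiple}-multiple-in-{k}-territories"


def classify_constellation(counts: Mapping, patient_id: object | None = None) -> ConstellationLabel:
    """Classify one patient's per-territory lesion counts.

    Parameters
    ----------
    counts
        Mapping from territory (``Territory``, code string, or count-column
        name) to a non-negative lesion count. Missing territories count 0.
    patient_id
        Used only to make the zero-lesion error message traceable.

    Raises
    ------
    ValidationError
        If the total lesion count is zero (the analysis admits only
        patients with a discernible acute infarct) or a count is negative.
    """
    c = _normalize_counts(counts)
    involved = [t for t in TERRITORY_ORDER if c.get(t, 0) >= 1]
    n_lesions = sum(c.get(t, 0) for t in TERRITORY_ORDER)
    if n_lesions == 0:
        who = f" (patient {patient_id})" if patient_id is not None else ""
        raise ValidationError(f"invalid record{who}: total lesion count is zero")

    statuses = tuple(sorted("single" if c[t] == 1 else "multiple" for t in involved))
    sides = {t.side for t in involved if t.side != "midline"}
    compartments = {t.compartment for t in involved}
    circulations = {t.circulation for t in involved}
    return ConstellationLabel(
        n_lesions=n_lesions,
        n_territories=len(involved),
        mal=n_lesions > 1,
        category=category_label(statuses),
        bilateral=sides == {"left", "right"},
        supra_and_infra=compartments == {"supratentorial", "infratentorial"},
        ant_and_post=circulations == {"anterior", "posterior"},
        circulation="both" if len(circulations) == 2 else next(iter(circulations)),
        statuses=statuses,
    )


def _iter_count_rows(cohort) -> Iterable[Mapping]:
    """Yield per-patient count mappings from a frame or a sequence of mappings."""
    if isinstance(cohort, pd.DataFrame):
        present = [col for col in COUNT_COLUMNS if col in cohort.columns]
        if not present:
            raise ValidationError("cohort frame has no territory count columns")
        for row in cohort[present].itertuples(index=False):
            yield dict(zip(present, row))
    else:
        yield from cohort


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_territories(cohort) -> pd.DataFrame:
    """Count, per territory, patients with a single vs multiple lesions *there*.

    A patient contributes a row entry to every territory where they have at
    least one lesion, and is counted "single" or "multiple" by the lesion
    count within that territory — not by their global single/multiple
    status. (A patient with one lesion in each of two territories is
    globally MAL but appears in the "single" column of both territories.)

    Returns a frame indexed by territory display name with columns
    ``n_single``, ``n_multiple`` and ``percent_multiple`` (one decimal,
    half-up; NaN for territories no patient involves).
    """
    rows = {t: [0, 0] for t in TERRITORY_ORDER}
    n_patients = 0
    for counts in _iter_count_rows(cohort):
        c = _normalize_counts(counts)
        if sum(c.values()) == 0:
            raise ValidationError("invalid record: total lesion count is zero")
        n_patients += 1
        for t, k in c.items():
            if k == 1:
                rows[t][0] += 1
            elif k >= 2:
                rows[t][1] += 1
    if n_patients == 0:
        raise EmptyInputError("cannot tabulate an empty cohort")

    records = []
    for t in TERRITORY_ORDER:
        single, multiple = rows[t]
        total = single + multiple
        pct = round_half_up(100.0 * multiple / total) if total else float("nan")
        records.append(
            {
                "territory": t.display_name,
                "n_single": single,
                "n_multiple": multiple,
                "percent_multiple": pct,
            }
        )
    return pd.DataFrame.from_records(records).set_index("territory")


def constellation_frequencies(cohort) -> dict:
    """Tabulate constellation categories and marginal flags for a cohort.

    Returns a dict with:

    * ``n`` — cohort size
    * ``categories`` — mapping category label -> ``{"count", "percent"}``;
      the counts partition the cohort
    * ``marginals`` — counts and percents for ``mal``, ``multi_territory``,
      ``bilateral``, ``supra_and_infra`` and ``ant_and_post``

    Percents are half-up rounded to one decimal, matching report style.
    """
    labels = [
        classify_constellation(counts) for counts in _iter_count_rows(cohort)
    ]
    n = len(labels)
    if n == 0:
        raise EmptyInputError("cannot compute frequencies of an empty cohort")

    categories: dict[str, int] = {}
    for lab in labels:
        categories[lab.category] = categories.get(lab.category, 0) + 1

    def _entry(count: int) -> dict:
        return {"count": count, "percent": round_half_up(100.0 * count / n)}

    marginals = {
        "mal": _entry(sum(lab.mal for lab in labels)),
        "multi_territory": _entry(sum(lab.n_territories > 1 for lab in labels)),
        "bilateral": _entry(sum(lab.bilateral for lab in labels)),
        "supra_and_infra": _entry(sum(lab.supra_and_infra for lab in labels)),
        "ant_and_post": _entry(sum(lab.ant_and_post for lab in labels)),
    }
    return {
        "n": n,
        "categories": {cat: _entry(cnt) for cat, cnt in sorted(categories.items())},
        "marginals": marginals,
    }


def label_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append constellation label columns to a cohort frame.

    Adds the columns in :data:`LABEL_COLUMNS`; returns a new frame.
    """
    if cohort.empty:
        raise EmptyInputError("cannot label an empty cohort")
    present = [col for col in COUNT_COLUMNS if col in cohort.columns]
    labels = []
    for idx, row in zip(cohort.index, cohort[present].itertuples(index=False)):
        pid = cohort.at[idx, "patient_id"] if "patient_id" in cohort.columns else idx
        labels.append(classify_constellation(dict(zip(present, row)), patient_id=pid))
    out = cohort.copy()
    for col in LABEL_COLUMNS:
        out[col] = [getattr(lab, col) for lab in labels]
    return out
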