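"""The nine vascular supply territories.

Acute ischemic lesions are assigned to the anterior cerebral artery (ACA),
middle cerebral artery (MCA) and posterior cerebral artery (PCA)
territories, coded separately per hemisphere, and to the vertebrobasilar
territory split into left/right cerebellum and a midline brainstem region.
Each territory carries three fixed anatomical attributes: side, tentorial
compartment and circulation. ACA and MCA belong to the anterior
circulation; PCA, cerebellum and brainstem to the posterior circulation.
ACA/MCA/PCA are supratentorial; cerebellum and brainstem infratentorial.
The brainstem is midline and therefore never contributes to bilaterality.
"""

from __future__ import annotations

import enum


class Territory(enum.Enum):
    ACA_LEFT = "aca_l"
    ACA_RIGHT = "aca_r"
    MCA_LEFT = "mca_l"
    MCA_RIGHT = "mca_r"
    PCA_LEFT = "pca_l"
    PCA_RIGHT = "pca_r"
    CEREBELLUM_LEFT = "cereb_l"
    CEREBELLUM_RIGHT = "cereb_r"
    BRAINSTEM = "brainstem"

    @property
    def column(self) -> str:
        """Name of the lesion-count column in cohort files (``n_<code>``)."""
        return f"n_{self.value}"

    @property
    def side(self) -> str:
        if self is Territory.BRAINSTEM:
            return "midline"
        return "left" if self.value.endswith("_l") else "right"

    @property
    def compartment(self) -> str:
        if self in (Territory.CEREBELLUM_LEFT, Territory.CEREBELLUM_RIGHT, Territory.BRAINSTEM):
            return "infratentorial"
        return "supratentorial"

    @property
    def circulation(self) -> str:
        if self in (Territory.ACA_LEFT, Territory.ACA_RIGHT, Territory.MCA_LEFT, Territory.MCA_RIGHT):
            return "anterior"
        return "posterior"

    @property
    def display_name(self) -> str:
        base = {
            "aca": "ACA", "mca": "MCA", "pca": "PCA", "cereb": "Cereb",
        }
        if self is Territory.BRAINSTEM:
            return "Brainstem"
        stem, side = self.value.rsplit("_", 1)
        return f"{'Left' if side == 'l' else 'Right'} {base[stem]}"


#: Territories in Table-style display order (left/right pairs, brainstem last).
TERRITORY_ORDER: tuple[Territory, ...] = (
    Territory.ACA_LEFT,
    Territory.ACA_RIGHT,
    Territory.MCA_LEFT,
    Territory.MCA_RIGHT,
    Territory.PCA_LEFT,
    Territory.PCA_RIGHT,
    Territory.CEREBELLUM_LEFT,
    Territory.CEREBELLUM_RIGHT,
    Territory.BRAINSTEM,
)

#: Column names of the per-territory lesion counts, in schema order.
COUNT_COLUMNS: tuple[str, ...] = tuple(t.column for t in TERRITORY_ORDER)
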