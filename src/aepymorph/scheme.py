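"""Measurement schemes for aepyornithid hind-limb long bones.

Three skeletal elements are measured: femur (codes F1-F20), tibiotarsus
(Tt1-Tt21) and tarsometatarsus (Tmt1-Tmt44).  Each code denotes a linear
measurement in millimetres.  Two codes (F15, Tt21) occur in published
per-taxon measurement tables but carry no anatomical definition in the
published measurement diagram; they are registered with an explicit
"definition unknown" description rather than guessed at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum


class Element(str, Enum):
    """Skeletal element of the avian hind limb."""

    FEMUR = "femur"
    TIBIOTARSUS = "tibiotarsus"
    TARSOMETATARSUS = "tarsometatarsus"


UNKNOWN_DEFINITION = "not defined in the published measurement diagram"

_FEMUR_DESCRIPTIONS = {
    "F1": "total length",
    "F2": "minimum midshaft width",
    "F3": "circumference at minimum midshaft width",
    "F4": "maximum midshaft width",
    "F5": "circumference of caput femoris",
    "F6": "dorsoventral diameter of caput femoris",
    "F7": "proximo-distal diameter of caput femoris",
    "F8": "dorsoventral thickness of trochanter femoris",
    "F9": "maximum width of distal condyles",
    "F10": "maximum height of condylus medialis",
    "F11": "maximum height of condylus lateralis",
    "F12": "sulcus patellaris to trochanter femoris",
    "F13": "trochanter femoris to condylus medialis",
    "F14": "proximo-medial extreme of caput femoris to condylus lateralis",
    "F15": UNKNOWN_DEFINITION,
    "F16": "medio-lateral length of caput femoris",
    "F17": "dorsal extremity of crista trochanteris to dorsal extremity of caput femoris",
    "F18": "ventral extremity of crista trochanteris to ventral extremity of caput femoris",
    "F19": "trochlea fibularis width",
    "F20": "distance between medial and condylus lateralis",
}

_TIBIOTARSUS_DESCRIPTIONS = {
    "Tt1": "total length",
    "Tt2": "minimum midshaft width",
    "Tt3": "circumference at Tt2",
    "Tt4": "maximum midshaft width",
    "Tt5": "width of condyles",
    "Tt6": "maximum height, condylus medialis",
    "Tt7": "maximum height, condylus lateralis",
    "Tt8": "maximum width of head, including crest",
    "Tt9": "width of proximal end, including crista cnemialis cranialis",
    "Tt10": "width of head",
    "Tt11": "distance between cnemial crests",
    "Tt12": "extreme width of posterior groove",
    "Tt13": "posterior groove to external condyle",
    "Tt14": "posterior groove height to external condyle",
    "Tt15": "external condyle width",
    "Tt16": "external condyle height",
    "Tt17": "outer cnemial crest width",
    "Tt18": "outer crista cnemialis lateralis height",
    "Tt19": "total outer crista cnemialis lateralis ridge length",
    "Tt20": "tibia scar",
    "Tt21": UNKNOWN_DEFINITION,
}

_TMT_DESCRIPTIONS = {
    "Tmt1": "length",
    "Tmt2": "minimum shaft thickness (not midshaft)",
    "Tmt3": "shaft width at Tmt2",
    "Tmt4": "trochlea III width",
    "Tmt5": "width (all trochleae)",
    "Tmt6": "head height at midpoint, including ridge",
    "Tmt7": "maximum height, proximal end of metatarsal II",
    "Tmt8": "maximum height, proximal end of metatarsal IV",
    "Tmt9": "head width",
    "Tmt10": "inside curve (plantar) across three trochleae",
    "Tmt11": "outside curve (cranial) across three trochleae",
    "Tmt12": "trochlea III, plantar width",
    "Tmt13": "trochlea III, cranial width",
    "Tmt14": "trochlea II, medial thickness",
    "Tmt15": "trochlea II, central thickness",
    "Tmt16": "trochlea II, lateral thickness",
    "Tmt17": "trochlea III, medial thickness",
    "Tmt18": "trochlea III, central thickness",
    "Tmt19": "trochlea III, lateral thickness",
    "Tmt20": "trochlea IV, medial thickness",
    "Tmt21": "trochlea IV, central thickness",
    "Tmt22": "trochlea IV, lateral thickness",
    "Tmt23": "trochlea III, diagonal length",
    "Tmt24": "trochlea IV, diagonal length",
    "Tmt25": "trochlea III, medial length, outside to notch",
    "Tmt26": "trochlea III, medial length, outside with notch",
    "Tmt27": "trochlea III, medio-cranial length",
    "Tmt28": "trochlea III, lateral-cranial length",
    "Tmt29": "trochlea III, lateral length, outside",
    "Tmt30": "trochlea II length",
    "Tmt31": "trochlea IV length",
    "Tmt32": "trochlea III, cranial (peak to peak) notch width",
    "Tmt33": "total width at foramina",
    "Tmt34": "foramina width",
    "Tmt35": "maximum anterior-posterior depth of external cotyle",
    "Tmt36": "minimum depth of head",
    "Tmt37": "maximum depth at hypotarsal ridge (no ridge)",
    "Tmt38": "maximum depth at hypotarsal ridge (inclusive of ridge)",
    "Tmt39": "proximal-lateral extreme of head to hypotarsal ridge extreme",
    "Tmt40": "proximal-medial extreme of head to hypotarsal ridge extreme",
    "Tmt41": "length, trochlea II to head",
    "Tmt42": "length, trochlea IV to head",
    "Tmt43": "diagonal length, trochlea II to head",
    "Tmt44": "diagonal length, trochlea IV to head",
}

# Anatomically structured missingness: a break at one end of a bone removes
# every measurement taken on that end, and any span measurement (total or
# end-to-end lengths) that needs both ends intact.  Groupings follow the
# anatomical definitions above.
_BREAKAGE_BLOCKS = {
    Element.FEMUR: {
        "proximal": ["F5", "F6", "F7", "F8", "F16", "F17", "F18"],
        "distal": ["F9", "F10", "F11", "F19", "F20"],
        "shaft": ["F2", "F3", "F4"],
        "span": ["F1", "F12", "F13", "F14", "F15"],
    },
    Element.TIBIOTARSUS: {
        "proximal": ["Tt8", "Tt9", "Tt10", "Tt11", "Tt12", "Tt17", "Tt18", "Tt19"],
        "distal": ["Tt5", "Tt6", "Tt7", "Tt13", "Tt14", "Tt15", "Tt16", "Tt20"],
        "shaft": ["Tt2", "Tt3", "Tt4"],
        "span": ["Tt1", "Tt21"],
    },
    Element.TARSOMETATARSUS: {
        "proximal": ["Tmt6", "Tmt7", "Tmt8", "Tmt9", "Tmt33", "Tmt34", "Tmt35",
                     "Tmt36", "Tmt37", "Tmt38", "Tmt39", "Tmt40"],
        "distal": [f"Tmt{i}" for i in range(10, 33)] + ["Tmt4", "Tmt5"],
        "shaft": ["Tmt2", "Tmt3"],
        "span": ["Tmt1", "Tmt41", "Tmt42", "Tmt43", "Tmt44"],
    },
}

_CODE_PATTERN = re.compile(r"^(F|Tt|Tmt)\d+$")


@dataclass(frozen=True)
class MeasurementScheme:
    """Ordered registry of measurement codes for one skeletal element."""

    element: Element
    codes: tuple[str, ...]
    descriptions: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError(f"duplicate codes in scheme for {self.element.value}")

    @property
    def n_codes(self) -> int:
        return len(self.codes)

    def breakage_blocks(self) -> dict[str, list[str]]:
        """Code groups lost together when a bone breaks (proximal end,
        distal end, shaft, and the span measurements needing both ends)."""
        return {k: list(v) for k, v in _BREAKAGE_BLOCKS[self.element].items()}

    def describe(self, code: str) -> str:
        return self.descriptions[code]


_SCHEMES: dict[Element, MeasurementScheme] = {
    Element.FEMUR: MeasurementScheme(
        Element.FEMUR,
        tuple(f"F{i}" for i in range(1, 21)),
        _FEMUR_DESCRIPTIONS,
    ),
    Element.TIBIOTARSUS: MeasurementScheme(
        Element.TIBIOTARSUS,
        tuple(f"Tt{i}" for i in range(1, 22)),
        _TIBIOTARSUS_DESCRIPTIONS,
    ),
    Element.TARSOMETATARSUS: MeasurementScheme(
        Element.TARSOMETATARSUS,
        tuple(f"Tmt{i}" for i in range(1, 45)),
        _TMT_DESCRIPTIONS,
    ),
}


def get_scheme(element: Element | str) -> MeasurementScheme:
    """Return the measurement scheme for an element."""
    return _SCHEMES[Element(element)]


def looks_like_code(name: str) -> bool:
    """True if a column name has the shape of a measurement code
    (used to distinguish mistyped codes from ordinary metadata columns)."""
    return bool(_CODE_PATTERN.match(name))
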