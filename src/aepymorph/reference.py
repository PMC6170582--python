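"""Published per-taxon reference data for the four recognized aepyornithid taxa.

Bundled as plain CSVs: per-taxon min-max measurement ranges for femora and
tarsometatarsi, and single type-specimen values for tibiotarsi.  Also
registers the published discrete diagnostic intervals used to place
literature specimens, and the type-specimen seniority table (name,
publication year/month, element, cluster) used to resolve cluster names.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .scheme import Element, get_scheme

#: The four recognized taxa, in increasing body-size order.  This order is
#: also the interpolation axis for per-taxon values missing from the
#: published tables.
TAXA = (
    "Mullerornis modestus",
    "Aepyornis hildebrandti",
    "Aepyornis maximus",
    "Vorombe titan",
)

#: Morphometric cluster ids in the same order as TAXA.
CLUSTER_IDS = ("1", "2a", "2b", "3")


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("aepymorph.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_printed_ranges(element: Element | str) -> pd.DataFrame:
    """Tidy table of published per-taxon ranges: code, taxon, min_mm, max_mm.

    For the tibiotarsus only single type-specimen values are published, so
    min_mm == max_mm there and the sample-size column is absent.
    """
    element = Element(element)
    if element == Element.FEMUR:
        return _read_data("femur_ranges.csv")
    if element == Element.TARSOMETATARSUS:
        return _read_data("tarsometatarsus_ranges.csv")
    df = _read_data("tibiotarsus_values.csv")
    return df.assign(min_mm=df["value_mm"], max_mm=df["value_mm"]).drop(
        columns="value_mm"
    )


def _interpolate_across_taxa(values: pd.DataFrame) -> pd.DataFrame:
    """Fill per-taxon gaps by linear interpolation (and edge extrapolation)
    along the taxon size order; codes with no data in any taxon stay NaN."""
    out = values.copy()
    x_all = np.arange(len(TAXA), dtype=float)
    for code in out.index:
        row = out.loc[code].to_numpy(dtype=float)
        have = np.isfinite(row)
        if have.sum() == 0 or have.all():
            continue
        xs, ys = x_all[have], row[have]
        if have.sum() == 1:
            out.loc[code] = ys[0]
            continue
        # interior gaps: piecewise linear; edges: extend the nearest segment
        fit = np.interp(x_all, xs, ys)
        slope_lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
        slope_hi = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        fit[x_all < xs[0]] = ys[0] + slope_lo * (x_all[x_all < xs[0]] - xs[0])
        fit[x_all > xs[-1]] = ys[-1] + slope_hi * (x_all[x_all > xs[-1]] - xs[-1])
        out.loc[code] = fit
    return out


def _wide(element: Element, stat) -> pd.DataFrame:
    ranges = load_printed_ranges(element)
    scheme = get_scheme(element)
    wide = pd.DataFrame(index=list(scheme.codes), columns=list(TAXA), dtype=float)
    for _, row in ranges.iterrows():
        wide.loc[row["code"], row["taxon"]] = stat(row)
    return wide


def printed_midpoints(element: Element | str) -> pd.DataFrame:
    """codes x taxa matrix of range midpoints (mm), gaps interpolated.

    The tibiotarsal Tt15 has no published value for any taxon; it is filled
    as the per-taxon mean of its anatomical neighbours Tt14 and Tt16.
    """
    element = Element(element)
    mids = _interpolate_across_taxa(
        _wide(element, lambda r: (r["min_mm"] + r["max_mm"]) / 2.0)
    )
    if element == Element.TIBIOTARSUS and mids.loc["Tt15"].isna().all():
        mids.loc["Tt15"] = (mids.loc["Tt14"] + mids.loc["Tt16"]) / 2.0
    return mids


def printed_widths(element: Element | str) -> pd.DataFrame:
    """codes x taxa matrix of range widths (mm), gaps interpolated.

    Tibiotarsal "ranges" are single specimens (zero width); callers needing
    a dispersion default should fall back to a fraction of the mean.
    """
    element = Element(element)
    widths = _interpolate_across_taxa(
        _wide(element, lambda r: r["max_mm"] - r["min_mm"])
    )
    if element == Element.TIBIOTARSUS:
        widths = widths.fillna(0.0)
    return widths


# Published discrete diagnostic intervals (mm) used to place literature
# specimens that could not be measured directly.  Keys are cluster ids.
DIAGNOSTIC_INTERVALS: dict[tuple[Element, str], dict[str, tuple[float, float]]] = {
    # extreme breadth across the trochlear condyles of the tarsometatarsus
    (Element.TARSOMETATARSUS, "Tmt5"): {
        "1": (65.0, 79.24),
        "2a": (105.0, 118.0),
        "2b": (125.18, 140.2),
        "3": (164.0, 178.0),
    },
    # proximal width of the tarsometatarsus
    (Element.TARSOMETATARSUS, "Tmt9"): {
        "1": (65.8, 81.46),
        "2a": (99.7, 123.1),
        "2b": (140.3, 150.5),
        "3": (173.0, 184.0),
    },
    # minimum femoral shaft circumference
    (Element.FEMUR, "F3"): {
        "1": (114.0, 158.0),
        "2a": (172.0, 210.0),
        "2b": (208.0, 254.0),
        "3": (253.0, 288.0),
    },
}


# Type specimens included in the morphometric clusters, with publication
# year/month of the species name each bears.  Months are only recorded where
# they matter for seniority (titan, January 1894, vs ingens, February 1894).
TYPE_SPECIMEN_TABLE = pd.DataFrame(
    [
        # taxon_name, pub_year, pub_month, element, cluster, role
        ("modestus", 1869, None, "femur", "1", "holotype"),
        ("hildebrandti", 1893, None, "femur", "2a", "syntype"),
        ("hildebrandti", 1893, None, "tarsometatarsus", "2a", "syntype"),
        ("agilis", 1894, None, "tibiotarsus", "1", "syntype"),
        ("rudis", 1894, None, "tibiotarsus", "1", "holotype"),
        ("gracilis", 1913, None, "femur", "2a", "holotype"),
        ("lentus", 1894, None, "tarsometatarsus", "2a", "holotype"),
        ("medius", 1869, None, "femur", "2b", "holotype"),
        ("cursor", 1894, None, "tarsometatarsus", "2b", "holotype"),
        ("maximus", 1851, None, "tarsometatarsus", "2b", "lectotype"),
        ("titan", 1894, 1, "femur", "3", "syntype"),
        ("titan", 1894, 1, "tibiotarsus", "3", "syntype"),
        ("ingens", 1894, 2, "tibiotarsus", "3", "syntype"),
        ("ingens", 1894, 2, "tarsometatarsus", "3", "syntype"),
    ],
    columns=["taxon_name", "pub_year", "pub_month", "element", "cluster", "role"],
)
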