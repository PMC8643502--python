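"""Destrieux cortical parcellation → cerebral lobe mapping.

The analysis partitions the 74 Destrieux (a2009s) cortical areas per
hemisphere into frontal (22), temporal (12), occipital (14) and parietal
(12) lobes — 60 analysed areas — and discards the 14 cingulate, insular
and medial-wall-adjacent labels that belong to none of the four lobes.
The mapping ships with the package as a TSV resource.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LOBES = ("frontal", "temporal", "occipital", "parietal")

#: lobe counts of the analysed partition, per hemisphere
EXPECTED_LOBE_COUNTS = {"frontal": 22, "temporal": 12, "occipital": 14, "parietal": 12}


def load_lobe_table(include_excluded: bool = False) -> pd.DataFrame:
    """Return the packaged area→lobe table.

    Parameters
    ----------
    include_excluded:
        If True, also return the 14 areas assigned to no lobe
        (``lobe == "none"``); by default only the 60 analysed areas.
    """
    ref = resources.files("diaschisis.data").joinpath("destrieux_lobes.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", dtype=str)
    if not include_excluded:
        table = table[table["lobe"] != "none"].reset_index(drop=True)
    return table


def lobe_of() -> dict[str, str]:
    """Mapping ``area_label → lobe`` over the 60 analysed areas."""
    table = load_lobe_table()
    return dict(zip(table["area_label"], table["lobe"]))


def areas_by_lobe() -> dict[str, list[str]]:
    """Mapping ``lobe → sorted list of area labels``."""
    table = load_lobe_table()
    return {
        lobe: sorted(table.loc[table["lobe"] == lobe, "area_label"])
        for lobe in LOBES
    }


def analysis_areas() -> list[str]:
    """The 60 analysed area labels, in atlas order."""
    return list(load_lobe_table()["area_label"])
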