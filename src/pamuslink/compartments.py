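"""Subcellular proteome remodeling summaries.

Proteins are binned into a controlled compartment vocabulary by parsing
UniProt-style "Subcellular location" strings, and per-compartment L2fc
distributions (n, median, IQR) summarise how each organelle's proteome
shifts under a contrast. Multi-location strings are resolved by
first-listed precedence by default; an opt-in multi-assign mode duplicates
the protein into every listed compartment.

The term -> compartment vocabulary ships as an editable TSV
(``data/compartment_map.tsv``): "chloroplast" is synonymised to plastid and
membrane sub-locations (thylakoid membrane, plasma membrane, ...) roll up
to "membrane". Note precedence acts on the location *segments*: in
"Plastid, chloroplast thylakoid membrane" the first segment ("Plastid")
wins, so the protein is plastidial, not membrane.
"""

from __future__ import annotations

import re
from importlib import resources

import numpy as np
import pandas as pd

UNANNOTATED = "unannotated"


def load_compartment_map(path=None) -> list[tuple[str, str]]:
    """Load the term->compartment vocabulary, longest terms first so that
    e.g. "thylakoid membrane" matches before bare "membrane"."""
    if path is None:
        src = resources.files("pamuslink.data").joinpath("compartment_map.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    pairs = [(str(t).lower(), str(c)) for t, c in
             zip(table["term"], table["compartment"])]
    return sorted(pairs, key=lambda tc: -len(tc[0]))


_SEGMENT_SPLIT = re.compile(r"[,;.]")


def _match_segment(segment: str, mapping) -> str | None:
    seg = segment.strip().lower()
    for term, comp in mapping:
        if term in seg:
            return comp
    return None


def assign_compartment(location_string: str, mapping=None,
                       multi: bool = False):
    """Map one location string to a compartment label (or labels).

    First-listed precedence: segments (split on commas/semicolons/periods)
    are scanned left to right and the first that matches the vocabulary
    decides. With ``multi=True`` every matching segment contributes and a
    de-duplicated list is returned. Unmatched or empty strings map to
    ``"unannotated"``.
    """
    if mapping is None:
        mapping = load_compartment_map()
    if location_string is None or (isinstance(location_string, float)
                                   and np.isnan(location_string)):
        location_string = ""
    segments = [s for s in _SEGMENT_SPLIT.split(str(location_string)) if s.strip()]
    hits = []
    for seg in segments:
        comp = _match_segment(seg, mapping)
        if comp is not None:
            if not multi:
                return comp
            if comp not in hits:
                hits.append(comp)
    if multi:
        return hits if hits else [UNANNOTATED]
    return UNANNOTATED


def assign_compartments(annotations: pd.DataFrame, mapping=None,
                        multi: bool = False) -> pd.DataFrame:
    """Assignment table (accession, compartment) for a whole annotation
    table; in multi mode a protein appears once per listed compartment."""
    if mapping is None:
        mapping = load_compartment_map()
    rows = []
    for acc, loc in zip(annotations["accession"],
                        annotations["subcellular_location"]):
        comps = assign_compartment(loc, mapping, multi=multi)
        if not multi:
            comps = [comps]
        rows.extend((acc, c) for c in comps)
    return pd.DataFrame(rows, columns=["accession", "compartment"])


def compartment_l2fc_distribution(de_table: pd.DataFrame,
                                  assignments: pd.DataFrame,
                                  contrast: str | None = None,
                                  min_size: int = 5) -> pd.DataFrame:
    """Per-compartment L2fc summary: n, median, IQR, small-group flag.

    Every protein in ``de_table`` must carry an assignment (possibly
    "unannotated"); proteins are joined on the ``feature`` column.
    """
    de = de_table if contrast is None else de_table[de_table["contrast"] == contrast]
    merged = de.merge(assignments, left_on="feature", right_on="accession",
                      how="left")
    merged["compartment"] = merged["compartment"].fillna(UNANNOTATED)
    rows = []
    for comp, sub in merged.groupby("compartment", sort=True):
        vals = sub["l2fc"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        q1, q3 = np.percentile(vals, [25, 75])
        rows.append({
            "contrast": sub["contrast"].iloc[0],
            "compartment": comp,
            "n": len(vals),
            "median_l2fc": float(np.median(vals)),
            "iqr": float(q3 - q1),
            "small_group": len(vals) < min_size,
        })
    return pd.DataFrame(rows)
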