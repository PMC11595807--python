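"""Reference annotation table for the C. crambe extract.

A curated table of the compounds reported from the ESI(+) UHPLC-HRMS/MS
profile of the sponge extract (guanidine alkaloids plus the two spiked
internal standards): observed m/z, retention time, charge state, proposed
formula, reported molecular-weight error, the major MS/MS fragments and the
proposed identification with its homologue parameters.  The table drives
validation (arithmetic reproduction, scaffold completeness) and the
"extract-like" synthetic manifest.

Rows whose ``shared_with`` column is set are co-eluting isobars annotated
from the same consensus MS2 scan as their partner row; they carry no
independent precursor measurement.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = ["load_reference", "parse_fragments", "SERIES_FAMILIES"]

SERIES_FAMILIES = ("A", "didehydroA", "A3", "B", "C", "B3", "C3")


def parse_fragments(text: str) -> list[tuple[float, int]]:
    """Parse a fragment column entry "mz:z|mz:z|..." into (mz, z) pairs."""
    if not isinstance(text, str) or not text.strip():
        return []
    out = []
    for tok in text.split("|"):
        mz, _, z = tok.partition(":")
        out.append((float(mz), int(z or 1)))
    return out


@lru_cache(maxsize=1)
def load_reference() -> pd.DataFrame:
    ref = resources.files("crambederep.data") / "crambe_reference_annotations.tsv"
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"idx": str, "shared_with": str})
    df["fragment_list"] = df["fragments"].map(parse_fragments)
    for col in ("m", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    df["is_series"] = df["family"].isin(SERIES_FAMILIES)
    df["shared"] = df["shared_with"].notna() & (df["shared_with"] != "")
    return df
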