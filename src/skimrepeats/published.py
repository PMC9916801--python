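"""Published study constants and the printed composition table.

These are the two species' 1C genome sizes, the fern substitution rate used
for LTR dating, the read numbers of the individual and comparative analyses,
and the per-lineage genomic proportions of the printed composition table.
They serve as *inputs* for internal-arithmetic checks (genome-size ratio,
coverages, superfamily shares, totals); nothing in the pipeline depends on
them.

Note the printed absolute [Gbp] columns of the original table are internally
inconsistent with the printed 1C values (each species' Gbp/% ratio implies
the other species' genome size), so only the [%] columns are carried here;
absolute amounts are always recomputed as gp_percent x own 1C / 100.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: 1C genome sizes, bp
GS_TANNENSIS = 73.19e9
GS_OBLIQUA = 147.29e9

#: substitution rate used for LTR insertion dating, per site per year
MU = 4.79e-9

#: reads per species in the individual analyses (100 nt after trimming)
INDIVIDUAL_READS = 4_000_000
#: reads per species in the GS-proportional comparative analysis
COMPARATIVE_READS = {"tannensis": 1_000_000, "obliqua": 2_000_000}

ANALYZED_READ_LEN = 100


def load_composition() -> pd.DataFrame:
    """Printed per-lineage genomic proportions (%) for both species."""
    with resources.files("skimrepeats.data").joinpath(
            "tmesipteris_composition.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def total_repeats_pct(df: pd.DataFrame, species: str) -> float:
    """Sum of the top-level repeat rows (everything except single copy)."""
    col = f"{species}_pct"
    return float(df.loc[df["level"] == "top", col].sum())


def single_copy_pct(df: pd.DataFrame, species: str) -> float:
    return 100.0 - total_repeats_pct(df, species)


def lineage_share_pct(df: pd.DataFrame, species: str, repeat_type: str,
                      lineage: str) -> float:
    """Share (%) of a lineage within its superfamily, e.g. Athila within
    Ty3/Gypsy."""
    col = f"{species}_pct"
    top = df[(df["repeat_type"] == repeat_type) & (df["level"] == "top")]
    lin = df[(df["repeat_type"] == repeat_type) & (df["lineage"] == lineage)]
    return 100.0 * float(lin[col].iloc[0]) / float(top[col].iloc[0])
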