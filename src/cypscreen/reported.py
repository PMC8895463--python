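"""Bundled published hit list of the food-compound CYP3A4 screen.

The table holds the 115 predicted inhibitors reported by the source study
with their printed descriptors (MW, AlogP, HBA, HBD), prediction index,
and literature IC50 annotation. ``lit_class`` carries the publication's own
potent/weak grouping of the 31 literature-annotated hits, which is what its
true/false-positive bookkeeping uses (one borderline compound, obacunone at
20.9 uM, was binned as potent there).
"""

from importlib import resources

import pandas as pd

# IC50s (uM) measured in vitro for two previously uncharacterized hits.
ASSAYED_IC50_UM = {"picropodophyllin": 3.5, "bilobetin": 12.9}


def load_reported_hits() -> pd.DataFrame:
    """The published 115-compound hit table as a DataFrame.

    Columns: foodb_id, cas, name, mw, alogp, hba, hbd, pred_index,
    lit_ic50 (text, may carry </> qualifiers; empty = uncharacterized),
    lit_class ('potent'/'weak'/empty).
    """
    with resources.files("cypscreen.data").joinpath("reported_hits.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"lit_ic50": str, "lit_class": str})
    df["lit_ic50"] = df["lit_ic50"].fillna("")
    df["lit_class"] = df["lit_class"].fillna("")
    return df
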