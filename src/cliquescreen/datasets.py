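"""Bundled reference data.

``bc_mcc_top5`` is the published top-5% maximal-clique-centrality ranking of
the 1,362-node breast-cancer interaction network (68 genes with competition
ranks and known-biomarker annotations).  It serves as an in-package worked
example and as the fixed gene universe for screening demonstrations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_bc_mcc_top5() -> pd.DataFrame:
    """Top-5% MCC ranking table: gene, mcc_rank, is_biomarker."""
    ref = resources.files("cliquescreen.data").joinpath("bc_mcc_top5.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
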