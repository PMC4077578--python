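"""Published benchmark misclassification rates bundled with the package.

Sixteen manually gated diffuse large B-cell lymphoma (DLBCL) samples from
the flowCAP-I challenge were clustered by several automated gating
methods; the per-sample misclassification rates against the manual gates
are shipped here as two tables.  The "joint" table compares the three
methods that register populations across the batch (JCM, HDPGMM, FLAME
with post-hoc meta-clustering); the "single" table compares per-sample
(-I) and pooled (-P) variants of FLAME, flowClust and SWIFT.  These feed
the table-aggregation utilities and give the reported headline summary
statistics without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_dlbcl_mcr"]


def load_dlbcl_mcr(which: str = "joint") -> pd.DataFrame:
    """Load one of the bundled DLBCL MCR tables ('joint' or 'single').

    Returns a DataFrame indexed by sample id with one column per method.
    """
    if which not in ("joint", "single"):
        raise ValueError("which must be 'joint' or 'single'")
    ref = resources.files("jcmflow").joinpath(f"data/dlbcl_mcr_{which}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="sample")
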