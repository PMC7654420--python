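"""The published 18-pair pancreatic-cancer signature, bundled for scoring.

The package ships the 18 immune-gene pairs and lasso-Cox coefficients of a
published pancreatic-adenocarcinoma prognostic signature (trained on a
TCGA RNA-seq cohort, validated on an independent array-based cohort).  It
serves as a ready-made worked example and
as a fixed oracle for the scoring rule: the risk score of a sample is the
coefficient-weighted sum of its pair indicators, so hand-constructed
indicator patterns have exactly computable scores.
"""

from __future__ import annotations

from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Signature
from .pairs import Pair

__all__ = ["load_pancreatic_signature", "exemplar_expression"]


def load_pancreatic_signature() -> Signature:
    """The bundled 18-pair signature with its published coefficients."""
    with resources.files("irgpsig.data").joinpath(
            "pancreatic_18_pair_signature.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    entries = [(str(r.gene_a), str(r.gene_b), float(r.coefficient))
               for r in df.itertuples()]
    return Signature(entries, {"source": "published pancreatic-cancer signature"})


def exemplar_expression(sig: Signature, active: Sequence[Pair],
                        sample_id: str = "S0") -> pd.DataFrame:
    """A one-sample expression matrix realizing a chosen indicator pattern.

    Every signature pair in ``active`` scores 1 (first gene strictly
    higher) and every other signature pair scores 0 (first gene strictly
    lower) — no gene of this signature appears on both sides of a pair, so
    a two-level value assignment suffices and no ties are involved.
    """
    active = set(active)
    unknown = active - set(sig.pairs)
    if unknown:
        raise ValueError(f"pair {next(iter(unknown))} is not in the signature")
    values: dict[str, float] = {}

    def _set(gene: str, val: float) -> None:
        if values.setdefault(gene, val) != val:
            raise ValueError(
                f"gene {gene!r} needs conflicting values; pattern not "
                "realizable by a two-level assignment")

    for a, b in sig.pairs:
        hi, lo = (a, b) if (a, b) in active else (b, a)
        _set(hi, 2.0)
        _set(lo, 1.0)
    genes = sig.genes
    return pd.DataFrame({sample_id: [values[g] for g in genes]},
                        index=pd.Index(genes, name="gene"))
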