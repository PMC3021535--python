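"""Bundled reference tables from the published study, used as analysis inputs.

Three small text tables ship with the package:

* ``top_sites.tsv`` — the strongest bound segments (>= 30-fold over whole-cell
  extract) with their peak P[Xbar], nearest genes, cytological band and, where
  observed, the polytene staining intensity of that locus.
* ``regulated_bound_genes.tsv`` — the HSF-bound, heat-regulated genes with
  per-system fold changes and FDR-adjusted p-values (cells and larvae).
* ``published_counts.json`` — summary counts: the insulator-motif/induction
  contingency table and the per-system differential-expression set sizes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as hio


def _data_path(name: str):
    return resources.files("hsfchip.data").joinpath(name)


def load_top_sites() -> pd.DataFrame:
    with resources.as_file(_data_path("top_sites.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_regulated_bound_genes() -> pd.DataFrame:
    with resources.as_file(_data_path("regulated_bound_genes.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def published_counts() -> dict:
    with resources.as_file(_data_path("published_counts.json")) as path:
        return hio.read_json(path)


def regulated_bound_long() -> pd.DataFrame:
    """The bound-gene expression table in long (gene, system, fold, p) form."""
    wide = load_regulated_bound_genes()
    rows = []
    for _, r in wide.iterrows():
        rows.append(
            {
                "gene_id": r["gene"],
                "system": "cells",
                "fold_change": float(r["fold_cells"]),
                "fdr_p": float(r["p_cells"]),
            }
        )
        rows.append(
            {
                "gene_id": r["gene"],
                "system": "larvae",
                "fold_change": float(r["fold_larvae"]),
                "fdr_p": float(r["p_larvae"]),
            }
        )
    return pd.DataFrame(rows)


def beaf_contingency_sets() -> dict[str, set[str]]:
    """Promoter gene-id sets realizing the published contingency counts.

    Membership identities are synthetic (``ind001``, ``non001``, ...); only
    the overlap cardinalities are meaningful. Within each induction group the
    "both" genes come first so motif and external-binding sets nest
    consistently with the published "both" count.
    """
    counts = published_counts()["beaf_contingency"]
    out: dict[str, set[str]] = {}
    for group, prefix in (("induced", "ind"), ("noninduced", "non")):
        c = counts[group]
        members = [f"{prefix}{i:03d}" for i in range(c["total"])]
        motif = set(members[: c["motif"]])
        both = set(members[: c["both"]])
        extra_binding = c["external_binding"] - c["both"]
        binding = both | set(members[c["motif"] : c["motif"] + extra_binding])
        out[f"{group}_promoters"] = set(members)
        out[f"{group}_motif"] = motif
        out[f"{group}_binding"] = binding
    return {
        "induced_promoters": out["induced_promoters"],
        "noninduced_promoters": out["noninduced_promoters"],
        "motif_positive": out["induced_motif"] | out["noninduced_motif"],
        "externally_bound": out["induced_binding"] | out["noninduced_binding"],
    }
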