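"""Pathway completeness, auxotrophy prediction and gene-set rules.

Annotation hits (gene vs HMM model) are accepted when the protein covers at
least 65% of the model and the e-value is at most 1e-3; per (gene, model) only
the most significant hit is kept. A pathway is an ordered list of steps, each a
set of alternative KO-like model identifiers; completeness is the fraction of
steps with at least one accepted model in the genome. A genome is prototrophic
for a compound only when the biosynthesis pathway is fully complete — any
missing step marks an auxotroph. Gene-set rules capture minimal functional
units such as the cbb3-type cytochrome c oxidase subunits ccoN/ccoO/ccoP.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Set

import pandas as pd

ACCEPT_MIN_MODEL_COVERAGE = 65.0  # percent, inclusive
ACCEPT_MAX_EVALUE = 1e-3          # inclusive

HIT_COLUMNS = ["genome_id", "gene_id", "model_id", "e_value", "model_coverage"]

CBB3_MINIMAL_UNIT = {"K00404", "K00405", "K00407"}  # ccoN, ccoO, ccoP


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    name: str
    category: str
    steps: tuple  # tuple of frozensets of alternative model ids

    def __post_init__(self) -> None:
        if not self.steps or any(not s for s in self.steps):
            raise ValueError(f"pathway {self.pathway_id} has empty steps")

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def load_pathway_definitions(path=None) -> Dict[str, PathwayDefinition]:
    """Load the packaged (or a user-supplied) pathway-definition table.

    Format: TSV with columns pathway_id, name, category, step_index,
    model_ids (comma-separated alternatives for that step).
    """
    if path is None:
        path = resources.files("streamscan.data").joinpath("pathway_definitions.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    defs = {}
    for pwy_id, group in df.groupby("pathway_id", sort=False):
        group = group.sort_values("step_index")
        steps = tuple(frozenset(m.strip() for m in row.model_ids.split(","))
                      for row in group.itertuples())
        defs[pwy_id] = PathwayDefinition(pwy_id, group.iloc[0]["name"],
                                         group.iloc[0]["category"], steps)
    return defs


def accept_hits(hits: pd.DataFrame,
                min_coverage: float = ACCEPT_MIN_MODEL_COVERAGE,
                max_evalue: float = ACCEPT_MAX_EVALUE) -> pd.DataFrame:
    """Annotation acceptance rule; one best hit per (genome, gene, model).

    A hit is accepted iff model_coverage >= 65 and e_value <= 1e-3 (inclusive);
    duplicates keep the lowest e-value.
    """
    ok = hits[(hits["model_coverage"] >= min_coverage)
              & (hits["e_value"] <= max_evalue)]
    ok = ok.sort_values(["genome_id", "gene_id", "model_id", "e_value"])
    return ok.drop_duplicates(subset=["genome_id", "gene_id", "model_id"],
                              keep="first").reset_index(drop=True)


def apply_aliases(hits: pd.DataFrame, aliases: Dict[str, str]) -> pd.DataFrame:
    """Collapse multiple annotation namespaces (COG/TIGRFAM/Pfam) onto one.

    Applied after acceptance: the coverage rule is evaluated per source hit."""
    out = hits.copy()
    out["model_id"] = out["model_id"].map(lambda m: aliases.get(m, m))
    return out


def genome_model_sets(accepted: pd.DataFrame) -> Dict[str, Set[str]]:
    return {gid: set(group["model_id"])
            for gid, group in accepted.groupby("genome_id")}


def module_completeness(models: Set[str], pathway: PathwayDefinition) -> float:
    """Fraction of pathway steps with at least one accepted model present."""
    hit = sum(1 for step in pathway.steps if step & models)
    return hit / pathway.n_steps


def completeness_matrix(model_sets: Dict[str, Set[str]],
                        pathway_defs: Dict[str, PathwayDefinition]
                        ) -> pd.DataFrame:
    """Genome x pathway completeness fractions (columns in definition order)."""
    cols = list(pathway_defs)
    rows = {gid: [module_completeness(models, pathway_defs[p]) for p in cols]
            for gid, models in sorted(model_sets.items())}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def auxotrophy_calls(matrix: pd.DataFrame,
                     biosynthesis_ids: Sequence[str]) -> pd.DataFrame:
    """True = auxotroph. Prototrophy requires completeness exactly 1.0;
    a partially present biosynthesis pathway still marks an auxotroph."""
    missing = [p for p in biosynthesis_ids if p not in matrix.columns]
    if missing:
        raise KeyError(f"unknown pathway ids: {missing}")
    return matrix[list(biosynthesis_ids)] < 1.0


def gene_set_rule(models: Set[str], required: Set[str]) -> bool:
    """True iff every required model is present (minimal functional unit)."""
    if not required:
        raise ValueError("required model set must be non-empty")
    return required <= models


def presence_absence_matrix(matrix: pd.DataFrame,
                            pathway_defs: Optional[Dict[str, PathwayDefinition]] = None,
                            complete: float = 1.0, absent: float = 0.0
                            ) -> pd.DataFrame:
    """Categorical complete/partial/absent matrix, columns grouped by category."""
    labels = matrix.apply(
        lambda col: col.map(lambda v: "complete" if v >= complete
                            else ("absent" if v <= absent else "partial")))
    if pathway_defs:
        order = sorted((p for p in matrix.columns if p in pathway_defs),
                       key=lambda p: (pathway_defs[p].category, list(pathway_defs).index(p)))
        order += [p for p in matrix.columns if p not in pathway_defs]
        labels = labels[order]
    return labels


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="genome_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="genome_id")
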