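"""Actionability decision tree for selected candidate genes.

Each candidate needs either *inhibition* (log fold change > 0: the
gene is down in the knockout, so a compound should suppress its
product in tumour cells) or *activation* (log fold change < 0). The
compound-modality search the screen performed by hand — inhibitor /
antagonist literature search, secretion check, recombinant-protein
availability, activator / agonist search — enters here as boolean
annotation flags, making the tree deterministic and testable.

The panel is then refined: secreted growth factors, ECM components and
targets with known or contradictory effects are excluded, as are
targets for which no modality was found.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import pandas as pd

__all__ = [
    "TargetAnnotation",
    "TargetDecision",
    "decide_action",
    "build_panel",
    "load_reference_panel",
]

MODALITIES = (
    "small_molecule_inhibitor", "antibody", "recombinant_protein",
    "agonist", "none_found",
)
EXCLUSION_REASONS = ("secreted_factor", "ecm_component", "known_effect", "no_compound")


@dataclass(frozen=True)
class TargetAnnotation:
    """Per-gene inputs to the decision tree.

    ``inhibitor_is_antibody`` qualifies ``inhibitor_exists`` (some
    specific inhibitors are antibodies rather than small molecules);
    it has no effect when ``inhibitor_exists`` is False.
    """

    gene_id: str
    log_fold_change: float
    inhibitor_exists: bool = False
    inhibitor_is_antibody: bool = False
    secreted: bool = False
    recombinant_exists: bool = False
    activator_exists: bool = False
    is_growth_factor: bool = False
    is_ecm: bool = False
    known_or_contradictory: bool = False


@dataclass(frozen=True)
class TargetDecision:
    """Required action, compound modality, and panel disposition."""

    gene_id: str
    action: str  # inhibit | activate
    modality: str
    in_panel: bool
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.in_panel and (self.modality == "none_found"
                              or self.exclusion_reason is not None):
            raise ValueError("panel members must have a modality and no exclusion")


def decide_action(ann: TargetAnnotation) -> TargetDecision:
    """Run one annotation through the decision tree.

    lfc > 0 -> inhibit: a specific inhibitor gives a small-molecule (or
    antibody) modality; failing that, an available recombinant protein
    can act as an inhibitor (ligand saturation of an inhibitory
    receptor). lfc < 0 -> activate: a secreted product with an
    available recombinant is supplied directly; otherwise an agonist is
    used if one exists. Refinement flags then set the exclusion reason
    and drop the target from the panel. lfc == 0 is undecidable.
    """
    if ann.log_fold_change == 0:
        raise ValueError(f"{ann.gene_id}: log fold change of 0 is undecidable")

    if ann.log_fold_change > 0:
        action = "inhibit"
        if ann.inhibitor_exists:
            modality = "antibody" if ann.inhibitor_is_antibody else "small_molecule_inhibitor"
        elif ann.recombinant_exists:
            modality = "recombinant_protein"
        else:
            modality = "none_found"
    else:
        action = "activate"
        if ann.secreted and ann.recombinant_exists:
            modality = "recombinant_protein"
        elif ann.activator_exists:
            modality = "agonist"
        else:
            modality = "none_found"

    exclusion: str | None = None
    if modality == "none_found":
        exclusion = "no_compound"
    elif ann.known_or_contradictory:
        exclusion = "known_effect"
    elif ann.is_growth_factor and ann.secreted:
        exclusion = "secreted_factor"
    elif ann.is_ecm:
        exclusion = "ecm_component"

    return TargetDecision(
        gene_id=ann.gene_id, action=action, modality=modality,
        in_panel=exclusion is None, exclusion_reason=exclusion,
    )


def build_panel(
    decisions: Iterable[TargetDecision],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assemble the compound panel and count dispositions by action.

    Returns ``(panel, summary)`` where ``panel`` holds the in-panel
    decisions and ``summary`` maps action -> count.
    """
    decisions = list(decisions)
    panel = pd.DataFrame(
        [{"gene_id": d.gene_id, "action": d.action, "modality": d.modality}
         for d in decisions if d.in_panel],
        columns=["gene_id", "action", "modality"],
    )
    summary = {
        "inhibit": int((panel["action"] == "inhibit").sum()) if len(panel) else 0,
        "activate": int((panel["action"] == "activate").sum()) if len(panel) else 0,
        "excluded": sum(1 for d in decisions if not d.in_panel),
    }
    return panel, summary


_BOOL_COLS = (
    "inhibitor_exists", "inhibitor_is_antibody", "secreted",
    "recombinant_exists", "activator_exists", "is_growth_factor",
    "is_ecm", "known_or_contradictory",
)


def annotations_from_table(table: pd.DataFrame) -> list[TargetAnnotation]:
    """Build annotations from a TSV-style table with boolean columns."""
    anns = []
    for _, row in table.iterrows():
        kwargs = {c: bool(row[c]) for c in _BOOL_COLS if c in table.columns}
        anns.append(TargetAnnotation(
            gene_id=str(row["gene_id"]),
            log_fold_change=float(row["log_fold_change"]),
            **kwargs,
        ))
    return anns


def load_reference_panel() -> pd.DataFrame:
    """Bundled 18-target annotation fixture for the published panel.

    Encodes each compound/target pair with its action-determining sign
    of expression change and the modality flags of the manual searches.
    Expression magnitudes are placeholders (only the sign enters the
    tree).
    """
    ref = resources.files("foxscreen.data").joinpath("candidate_panel.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
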