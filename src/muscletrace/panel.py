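"""Gene panels for single-cell qPCR experiments.

A panel assigns every assayed gene one of three roles:

``control``
    Housekeeping genes expected in every intact cell; used both for the
    cell-quality filter and (a subset of them) for per-cell normalization.
``interest``
    The biological readout genes (here the myogenic program: upstream
    progenitor markers and downstream myogenic regulatory factors).
``exclusion``
    Markers of contaminating lineages; any detection discards the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

VALID_ROLES = ("control", "interest", "exclusion")

#: Housekeeping genes of the esophagus progenitor panel.
DEFAULT_CONTROLS = ("Tbp", "Actb", "Hprt", "Rpl13a", "Rps29")
#: Controls entering the per-cell housekeeping mean (Tbp is kept out).
DEFAULT_NORMALIZERS = ("Actb", "Rpl13a", "Rps29", "Hprt")
#: Myogenic readout genes: upstream progenitor block then downstream MRFs.
DEFAULT_INTEREST = ("Isl1", "Met", "Pax7", "Myf5", "Myod", "Myog", "Mrf4")
#: Neurogenic contamination markers.
DEFAULT_EXCLUSION = ("Pax3", "Lhx3")

#: Genes whose latent expression is planted as a positively correlated block
#: by the synthetic generator (co-expressed progenitor state).
UPSTREAM_BLOCK = ("Isl1", "Met", "Pax7", "Myf5")
DOWNSTREAM_BLOCK = ("Myod", "Myog", "Mrf4")


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene list with per-gene roles and the normalizer subset.

    Parameters
    ----------
    genes : tuple of str
        All panel genes, in matrix row order.
    roles : mapping gene -> {"control", "interest", "exclusion"}
        Exhaustive and disjoint role assignment.
    normalizers : tuple of str
        Subset of the control genes used for the per-cell housekeeping mean.
    """

    genes: tuple[str, ...]
    roles: Mapping[str, str]
    normalizers: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names in panel")
        missing = [g for g in self.genes if g not in self.roles]
        if missing:
            raise ValueError(f"genes without a role: {missing}")
        extra = [g for g in self.roles if g not in self.genes]
        if extra:
            raise ValueError(f"roles for genes not in panel: {extra}")
        bad = {g: r for g, r in self.roles.items() if r not in VALID_ROLES}
        if bad:
            raise ValueError(f"invalid roles {bad}; valid: {VALID_ROLES}")
        if not self.control_genes:
            raise ValueError("panel must contain at least one control gene")
        not_ctrl = [g for g in self.normalizers if self.roles.get(g) != "control"]
        if not_ctrl:
            raise ValueError(f"normalizers must be control genes, got {not_ctrl}")

    def _with_role(self, role: str) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.roles[g] == role)

    @property
    def control_genes(self) -> tuple[str, ...]:
        return self._with_role("control")

    @property
    def interest_genes(self) -> tuple[str, ...]:
        return self._with_role("interest")

    @property
    def exclusion_genes(self) -> tuple[str, ...]:
        return self._with_role("exclusion")

    @property
    def normalizer_genes(self) -> tuple[str, ...]:
        # Fall back to all controls when no explicit subset was given.
        return self.normalizers if self.normalizers else self.control_genes

    @classmethod
    def from_role_lists(
        cls,
        controls: Iterable[str],
        interest: Iterable[str],
        exclusion: Iterable[str] = (),
        normalizers: Iterable[str] | None = None,
    ) -> "GenePanel":
        controls = tuple(controls)
        interest = tuple(interest)
        exclusion = tuple(exclusion)
        roles: dict[str, str] = {}
        roles.update({g: "control" for g in controls})
        roles.update({g: "interest" for g in interest})
        roles.update({g: "exclusion" for g in exclusion})
        if len(roles) != len(controls) + len(interest) + len(exclusion):
            raise ValueError("a gene appears in more than one role list")
        genes = controls + interest + exclusion
        norm = tuple(normalizers) if normalizers is not None else controls
        return cls(genes=genes, roles=roles, normalizers=norm)


def default_panel() -> GenePanel:
    """The esophagus striated-muscle progenitor panel used throughout."""
    return GenePanel.from_role_lists(
        controls=DEFAULT_CONTROLS,
        interest=DEFAULT_INTEREST,
        exclusion=DEFAULT_EXCLUSION,
        normalizers=DEFAULT_NORMALIZERS,
    )
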