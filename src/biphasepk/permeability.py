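"""Effective human intestinal permeability from molecular descriptors.

The permeability model is a two-descriptor power law relating effective
jejunal permeability to a halogen-corrected molecular weight and a membrane
affinity supplied by lipophilicity::

    Peff [cm/s] = 265.8 * MW_eff**(-4.5) * MA,      MA = 10**logP

with ``MW_eff = MW - 17*nF - 22*nCl - 62*nBr - 98*nI`` (g/mol).  The raw
value is in cm/s and is reported here in cm/min (factor 60), the unit used
for gastrointestinal absorption rate constants (k_a = 2*Peff/r).

Halogens contribute disproportionately little to molecular volume relative
to their mass, hence the per-atom mass corrections.  For drugs whose
permeability was determined by another route (e.g. converted from a Caco-2
assay), an explicit ``peff_override`` bypasses the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "MoleculeDescriptor",
    "effective_mw",
    "peff",
    "peff_cm_s",
    "HALOGEN_MW_CORRECTION",
    "REFERENCE_DRUGS",
]

#: per-atom molecular-weight correction, g/mol
HALOGEN_MW_CORRECTION = {"F": 17.0, "Cl": 22.0, "Br": 62.0, "I": 98.0}

#: power-law prefactor (cm/s) and molecular-weight exponent
PEFF_PREFACTOR = 265.8
PEFF_MW_EXPONENT = -4.5


class DescriptorError(ValueError):
    """Raised for invalid molecular descriptors."""


@dataclass(frozen=True)
class MoleculeDescriptor:
    """Physicochemical descriptors of a drug molecule.

    ``pka`` entries are ``(value, 'acid'|'base')`` pairs; ``solubilities``
    maps a medium label to µg/mL.  ``peff_override`` (cm/min) short-circuits
    the permeability correlation.  ``is_prodrug_of`` names the active
    metabolite's descriptor for ester-hydrolysis-activated prodrugs.
    """

    name: str
    mw: float
    n_fluorine: int = 0
    n_chlorine: int = 0
    n_bromine: int = 0
    n_iodine: int = 0
    logp: Optional[float] = None
    pka: Optional[Sequence[tuple]] = None
    solubilities: Optional[Mapping[str, float]] = None
    peff_override: Optional[float] = None
    is_prodrug_of: Optional["MoleculeDescriptor"] = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise DescriptorError("mw must be > 0")
        for name in ("n_fluorine", "n_chlorine", "n_bromine", "n_iodine"):
            if getattr(self, name) < 0:
                raise DescriptorError(f"{name} must be >= 0")
        if self.peff_override is not None and self.peff_override <= 0:
            raise DescriptorError("peff_override must be > 0 (cm/min)")


def effective_mw(descriptor: MoleculeDescriptor) -> float:
    """Halogen-corrected molecular weight, g/mol."""
    corr = (HALOGEN_MW_CORRECTION["F"] * descriptor.n_fluorine
            + HALOGEN_MW_CORRECTION["Cl"] * descriptor.n_chlorine
            + HALOGEN_MW_CORRECTION["Br"] * descriptor.n_bromine
            + HALOGEN_MW_CORRECTION["I"] * descriptor.n_iodine)
    mw_eff = descriptor.mw - corr
    if mw_eff <= 0:
        raise DescriptorError(
            f"{descriptor.name}: halogen correction ({corr} g/mol) exceeds MW"
        )
    return mw_eff


def peff_cm_s(descriptor: MoleculeDescriptor) -> float:
    """Effective permeability in cm/s (raw correlation value)."""
    return peff(descriptor) / 60.0


def peff(descriptor: MoleculeDescriptor) -> float:
    """Effective human intestinal permeability, cm/min.

    Returns ``peff_override`` unchanged when present; otherwise evaluates the
    power law with membrane affinity ``MA = 10**logP``.
    """
    if descriptor.peff_override is not None:
        return float(descriptor.peff_override)
    if descriptor.logp is None:
        raise DescriptorError(
            f"{descriptor.name}: logp required when no peff_override is set"
        )
    mw_eff = effective_mw(descriptor)
    ma = 10.0 ** descriptor.logp
    return 60.0 * PEFF_PREFACTOR * mw_eff ** PEFF_MW_EXPONENT * ma


def _ug_ml(**media: float) -> Mapping[str, float]:
    return dict(media)


_FENOFIBRIC_ACID = MoleculeDescriptor(
    name="fenofibric acid",
    mw=318.75,          # C17H15ClO4
    n_chlorine=1,
    logp=3.0,
    pka=((4.0, "acid"),),
    solubilities=_ug_ml(buffer_ph68=1.04e3),
)

#: Descriptors of the six reference drug products (plus the fenofibrate
#: active metabolite).  MW from the molecular formula; logP, pKa and
#: solubilities from experimental characterization of the marketed products.
REFERENCE_DRUGS: Mapping[str, MoleculeDescriptor] = {
    "aprepitant": MoleculeDescriptor(
        name="aprepitant", mw=534.43, n_fluorine=7, logp=4.8,
        pka=((2.8, "base"),),
        solubilities=_ug_ml(hcl_01n=62.0, buffer_ph68=1.39, fassif_v2=14.0),
    ),
    "celecoxib": MoleculeDescriptor(
        name="celecoxib", mw=381.37, n_fluorine=3, logp=3.7,
        pka=((10.7, "acid"),),
        solubilities=_ug_ml(hcl_01n=2.67, buffer_ph68=1.76, fassif_v2=4.52),
    ),
    "fenofibrate": MoleculeDescriptor(
        name="fenofibrate", mw=360.83, n_chlorine=1, logp=5.4,
        solubilities=_ug_ml(hcl_01n=0.62, buffer_ph68=1.08, fassif_v2=1.03),
        is_prodrug_of=_FENOFIBRIC_ACID,
    ),
    "fenofibric acid": _FENOFIBRIC_ACID,
    "itraconazole": MoleculeDescriptor(
        name="itraconazole", mw=705.63, n_chlorine=2, logp=5.4,
        pka=((3.8, "base"),),
        solubilities=_ug_ml(hcl_01n=6.1, buffer_ph68=0.88, fassif_v2=0.60),
    ),
    "nimodipine": MoleculeDescriptor(
        name="nimodipine", mw=418.44, logp=3.5,
        pka=((2.6, "base"),),
        solubilities=_ug_ml(hcl_01n=3.21, buffer_ph68=2.90, fassif_v2=5.18),
        # permeability converted from a Caco-2 assay rather than the
        # correlation (the power law badly underpredicts this molecule)
        peff_override=6.00e-4,
    ),
    "ritonavir": MoleculeDescriptor(
        name="ritonavir", mw=720.94, logp=4.4,
        pka=((1.9, "base"), (2.5, "base")),
        solubilities=_ug_ml(hcl_01n=382.8, buffer_ph68=0.96, fassif_v2=4.3,
                            fessif_v2=18.5),
    ),
}

#: labelled doses of the reference drug products, mg
REFERENCE_DOSES_MG: Mapping[str, float] = {
    "aprepitant": 125.0,
    "celecoxib": 200.0,
    "fenofibrate": 200.0,
    "itraconazole": 100.0,
    "nimodipine": 30.0,
    "ritonavir": 100.0,
}

#: in vitro partitioning plateaus (fraction absorbed) of the reference
#: products.  For nimodipine the plateau (~0.35) is the fraction absorbed;
#: its oral bioavailability is tenfold lower (0.035) because ~90% of the
#: absorbed dose is extracted on the first liver passage.
REFERENCE_FA: Mapping[str, float] = {
    "aprepitant": 0.59,
    "celecoxib": 0.39,
    "fenofibrate": 0.46,
    "itraconazole": 0.16,
    "nimodipine": 0.35,
    "ritonavir": 0.80,
}
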