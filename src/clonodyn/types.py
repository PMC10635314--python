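"""Shared domain vocabulary: compartments, sample keys, error classes.

A *sample* throughout the package is one (patient, treatment cycle,
body compartment) combination: e.g. the CSF draw taken during cycle 3 of
patient UPN514's therapy, or the infused cell product (cycle 0 by
convention). Every canonical table carries the three sample-key columns.
"""

from __future__ import annotations

from dataclasses import dataclass

CSF = "CSF"
PBMC = "PBMC"
PRODUCT = "PRODUCT"
TUMOR = "TUMOR"
COMPARTMENTS = (CSF, PBMC, PRODUCT, TUMOR)

#: Column names identifying a sample in every canonical table.
SAMPLE_COLS = ["upn", "cycle", "compartment"]

#: Sentinel used for absent gene segments (matches common 10x exports).
NONE_GENE = "None"


class ClonodynError(Exception):
    """Base class for all package errors."""


class FormatError(ClonodynError):
    """A file does not conform to its declared dialect."""


class ValidationError(ClonodynError):
    """A value violates a domain constraint (range, enum, feasibility)."""


class IntegrityError(ClonodynError):
    """Cross-record consistency violated (duplicate keys, missing links)."""


class ConfigError(ClonodynError):
    """A run configuration references unknown entities or is incomplete."""


@dataclass(frozen=True)
class SampleKey:
    """Identity of one sequencing sample.

    Parameters
    ----------
    upn
        Unique patient number (trial subject identifier).
    cycle
        Treatment-cycle ordinal; 0 denotes pre-infusion material (the
        engineered cell product).
    compartment
        One of ``CSF``, ``PBMC``, ``PRODUCT``, ``TUMOR``.
    """

    upn: str
    cycle: int
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )
        if self.cycle < 0:
            raise ValidationError(f"cycle must be >= 0, got {self.cycle}")
        if self.compartment == PRODUCT and self.cycle != 0:
            raise ValidationError("PRODUCT samples are keyed to cycle 0")

    def as_dict(self) -> dict:
        return {"upn": self.upn, "cycle": self.cycle, "compartment": self.compartment}
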