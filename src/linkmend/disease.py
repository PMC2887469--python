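"""The parametric disease model for linkage and simulation.

A single-locus diallelic model: disease allele frequency ``q`` and a
penetrance vector ``(f0, f1, f2)`` giving the probability of being affected
with 0, 1 or 2 copies of the disease allele.  The default is the classic
rare-dominant configuration with reduced penetrance: f1 = f2 = 0.8,
f0 = 0 (no phenocopies), q = 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DiseaseModel:
    q: float = 1e-4
    f0: float = 0.0
    f1: float = 0.8
    f2: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"disease allele frequency must be in (0,1), got {self.q}")
        if not (0.0 <= self.f0 <= self.f1 <= self.f2 <= 1.0):
            raise ValueError(
                f"penetrances must satisfy 0 <= f0 <= f1 <= f2 <= 1, got "
                f"({self.f0}, {self.f1}, {self.f2})"
            )

    @property
    def penetrance(self) -> tuple[float, float, float]:
        return (self.f0, self.f1, self.f2)

    def phenotype_prob(self, n_copies: int, affected: bool) -> float:
        f = self.penetrance[n_copies]
        return f if affected else 1.0 - f


DOMINANT_REDUCED = DiseaseModel()
FULLY_PENETRANT_DOMINANT = DiseaseModel(q=1e-4, f0=0.0, f1=1.0, f2=1.0)
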