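"""The study's simulation-protocol roster and trajectory-time accounting.

Encodes the enhanced-sampling campaign design — which protocols (REMD or
simulated tempering), force fields, solvent models, replica counts and
repeat runs were applied to the nine-peptide data set — and derives the
cumulated trajectory time of each row and of the campaign totals from
first principles: length × replicas × runs × peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProtocolSpec", "MD_PROTOCOLS", "N_PEPTIDES", "cumulated_time_us", "time_accounting"]

N_PEPTIDES = 9

#: Trajectory length per replica in μs: 1 for REMD, 10 for ST.
TRAJ_LENGTH_US = {"REMD": 1.0, "ST": 10.0}


@dataclass(frozen=True)
class ProtocolSpec:
    protocol: str  # "REMD" or "ST"
    force_field: str
    solvent: str  # "implicit" or "explicit"
    replicas: int
    runs: int

    @property
    def tag(self) -> str:
        base = self.force_field if self.protocol == "REMD" else f"ST-{self.force_field}"
        return base + ("-exp" if self.solvent == "explicit" else "")


MD_PROTOCOLS: list[ProtocolSpec] = [
    ProtocolSpec("REMD", "Amber96", "implicit", 8, 5),
    ProtocolSpec("REMD", "Amber14", "implicit", 8, 5),
    ProtocolSpec("REMD", "RSFF2C", "implicit", 8, 5),
    ProtocolSpec("REMD", "RSFF2C", "explicit", 32, 1),
    ProtocolSpec("REMD", "Charmm36m", "implicit", 8, 2),
    ProtocolSpec("ST", "Amber96", "implicit", 1, 2),
    ProtocolSpec("ST", "Amber14", "implicit", 1, 1),
    ProtocolSpec("ST", "Amber14", "explicit", 1, 1),
    ProtocolSpec("ST", "Charmm36m", "implicit", 1, 1),
]


def cumulated_time_us(spec: ProtocolSpec, n_peptides: int = N_PEPTIDES) -> float:
    """Trajectory length × replicas × runs × peptides, in μs."""
    return TRAJ_LENGTH_US[spec.protocol] * spec.replicas * spec.runs * n_peptides


def time_accounting(n_peptides: int = N_PEPTIDES) -> dict:
    """Per-protocol cumulated times and campaign totals (μs)."""
    rows = {p.tag: cumulated_time_us(p, n_peptides) for p in MD_PROTOCOLS}
    # the three force fields given the full five-run REMD treatment
    full_remd_ff = ("Amber96", "Amber14", "RSFF2C")
    remd_implicit = sum(
        cumulated_time_us(p, n_peptides)
        for p in MD_PROTOCOLS
        if p.protocol == "REMD" and p.solvent == "implicit" and p.force_field in full_remd_ff
    )
    remd_explicit = sum(
        cumulated_time_us(p, n_peptides)
        for p in MD_PROTOCOLS
        if p.protocol == "REMD" and p.solvent == "explicit"
    )
    implicit = sum(
        cumulated_time_us(p, n_peptides) for p in MD_PROTOCOLS if p.solvent == "implicit"
    )
    explicit = sum(
        cumulated_time_us(p, n_peptides) for p in MD_PROTOCOLS if p.solvent == "explicit"
    )
    return {
        "per_protocol": rows,
        "remd_implicit_three_forcefields_us": remd_implicit,
        "remd_explicit_us": remd_explicit,
        "implicit_total_us": implicit,
        "explicit_total_us": explicit,
        "grand_total_us": implicit + explicit,
    }
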