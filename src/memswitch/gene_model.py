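"""Gene/probe geometry and rendering of nascent-transcript fluorescence.

Single-molecule FISH quantifies nascent transcription in "cytoplasmic
units" (C.U.): the fluorescence of one fully synthesized mRNA.  A
polymerase that has traversed part of the gene carries a nascent RNA
displaying only the probe binding sites already transcribed, so its
fractional brightness is (number of probe sites behind it) / (total
probes).  This module owns that conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["GeneModel", "make_uniform_gene", "nascent_signal"]


@dataclass(frozen=True)
class GeneModel:
    """A transcribed gene with an ordered smFISH probe layout.

    Parameters
    ----------
    transcript_length_nt
        Length of the transcribed template in nucleotides.  A Pol II at
        this coordinate has finished the transcript.
    probe_positions_nt
        Strictly increasing 1-based transcript coordinates, one per
        probe.  A probe contributes signal once a Pol II has reached
        (>=) its coordinate, i.e. once the binding site exists on the
        nascent RNA.
    """

    transcript_length_nt: int
    probe_positions_nt: tuple[int, ...]
    _positions_arr: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.transcript_length_nt <= 0:
            raise ValueError("transcript_length_nt must be positive")
        pos = tuple(int(p) for p in self.probe_positions_nt)
        if len(pos) == 0:
            raise ValueError("at least one probe is required")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("probe_positions_nt must be strictly increasing")
        if pos[0] < 1 or pos[-1] > self.transcript_length_nt:
            raise ValueError(
                "probe positions must lie in [1, transcript_length_nt]"
            )
        object.__setattr__(self, "probe_positions_nt", pos)
        object.__setattr__(
            self, "_positions_arr", np.asarray(pos, dtype=np.float64)
        )

    @property
    def n_probes(self) -> int:
        return len(self.probe_positions_nt)

    def probes_transcribed(self, polii_positions_nt) -> np.ndarray:
        """Number of probe binding sites behind each Pol II position."""
        pos = np.asarray(polii_positions_nt, dtype=np.float64)
        return np.searchsorted(self._positions_arr, pos, side="right")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "transcript_length_nt": self.transcript_length_nt,
            "probe_positions_nt": list(self.probe_positions_nt),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneModel":
        return cls(
            transcript_length_nt=int(d["transcript_length_nt"]),
            probe_positions_nt=tuple(d["probe_positions_nt"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GeneModel":
        return cls.from_dict(json.loads(s))


def make_uniform_gene(n_probes: int, transcript_length_nt: int) -> GeneModel:
    """Gene with ``n_probes`` evenly spaced probes, the last at the 3' end.

    Probe i (1-based) sits at round(i * L / n).  The default synthetic
    E74-like gene is ``make_uniform_gene(67, 4500)``; only the relative
    probe layout matters for C.U. rendering, not the true annotation.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if transcript_length_nt < n_probes:
        raise ValueError("transcript_length_nt must be >= n_probes")
    positions = tuple(
        int(round(i * transcript_length_nt / n_probes))
        for i in range(1, n_probes + 1)
    )
    return GeneModel(transcript_length_nt, positions)


DEFAULT_GENE = make_uniform_gene(67, 4500)


def nascent_signal(
    polii_positions: Sequence[float] | np.ndarray, gene: GeneModel
) -> float:
    """Total nascent fluorescence, in C.U., of the Pol IIs on one locus.

    Each polymerase contributes (probes at or behind its position) /
    n_probes, so a Pol II at or past the last probe counts as exactly
    one finished mRNA and an empty locus scores 0.
    """
    pos = np.asarray(list(polii_positions), dtype=np.float64)
    if pos.size == 0:
        return 0.0
    if np.any(pos < 0) or np.any(pos > gene.transcript_length_nt):
        raise ValueError(
            "Pol II position outside [0, transcript_length_nt]: "
            "invalid simulator state"
        )
    counts = gene.probes_transcribed(pos)
    return float(counts.sum()) / gene.n_probes
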