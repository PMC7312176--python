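"""Synthetic clustered-sequence generator for end-to-end testing.

Emulates a genotyping dataset: each cluster is an i.i.d.-uniform random
ancestor genome, and its members are descendants derived by independent
per-site substitutions (each site mutates with probability ``sub_rate`` to
a uniformly chosen *different* base).  Substitution-only (no indels), so
the expected Hamming distance between ancestor and descendant is exactly
``sub_rate * length``.

Randomness is driven by a single integer seed through per-record
``numpy.random.SeedSequence`` spawn keys ``(seed, cluster, member)``, so
enlarging the configuration never perturbs previously generated records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SequenceRecord
from .seqio import Dataset

__all__ = ["SimulationConfig", "random_sequence", "mutate", "make_clusters"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    n_clusters: int = 4
    per_cluster: int = 10
    length: int = 5000
    sub_rate: float = 0.01
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.per_cluster < 1 or self.length < 1:
            raise ValueError("n_clusters, per_cluster and length must be >= 1")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError("sub_rate must lie in [0, 1]")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, *key])))


def random_sequence(length: int, rng: np.random.Generator, rec_id: str = "seq") -> SequenceRecord:
    """An i.i.d. uniform ACGT sequence of the given length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    return SequenceRecord(rec_id, seq)


def mutate(
    record: SequenceRecord,
    sub_rate: float,
    rng: np.random.Generator,
    rec_id: str | None = None,
) -> SequenceRecord:
    """Substitute each site independently with probability ``sub_rate``.

    A substituted site always receives a *different* base (chosen uniformly
    from the other three), so ``sub_rate=1`` changes every site.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise ValueError("sub_rate must lie in [0, 1]")
    arr = np.frombuffer(record.seq.encode("ascii"), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(arr.shape[0]) < sub_rate)
    if hit.size:
        # shift by 1..3 in base-index space: uniformly a different base
        base_idx = np.searchsorted(_BASES, arr[hit])
        shift = rng.integers(1, 4, size=hit.size)
        arr[hit] = _BASES[(base_idx + shift) % 4]
    return SequenceRecord(rec_id or record.id, arr.tobytes().decode("ascii"))


def make_clusters(config: SimulationConfig) -> Dataset:
    """Generate ``n_clusters`` ancestors with ``per_cluster`` mutated
    descendants each; labels are the cluster names.

    Fully reproducible: the same config yields a bit-identical dataset.
    """
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    for c in range(config.n_clusters):
        cluster = f"cluster{c + 1}"
        ancestor = random_sequence(
            config.length, _rng(config.seed, c, 0), rec_id=f"{cluster}_anc"
        )
        for m in range(config.per_cluster):
            rid = f"{cluster}_m{m + 1}"
            rec = mutate(ancestor, config.sub_rate, _rng(config.seed, c, m + 1), rec_id=rid)
            records.append(rec)
            labels[rid] = cluster
    return Dataset(records=records, labels=labels)
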