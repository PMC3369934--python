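"""Synthetic read sets with planted ADR bins and known injected errors.

The generator emulates the structure the estimator consumes: a template
genome is fragmented into reads, a configurable number of templates are
duplicated into prefix-identical bins (the planted ADR clusters), and
per-base substitution / insertion / deletion errors are injected at
known, optionally position-dependent, rates with every event logged.
Background singleton reads exercise the abundance filter. Errors are
withheld from the planted prefixes by default so bins stay discoverable
by exact-prefix binning; error estimation only ever uses non-prefix
bases, so this does not touch the quantity being validated.

The ground-truth error rate of a dataset is the realized per-base event
rate over the non-prefix bases of the planted duplicate copies — exactly
the quantity the duplicate-inferred weighted total error estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from drisee.seqio import SequenceRead

BASES = np.array(list("ACGT"))
# OTHER[i] = the three bases != BASES[i]
_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

_MAX_FRAGMENT_RETRIES = 100


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Rates are per-base probabilities; ``position_ramp``, if given, is a
    callable mapping a 0-based read position to a rate multiplier (for
    position-dependent error, e.g. quality decay toward read ends).
    Length laws are strings: ``fixed:N`` or ``lognormal:mu,sigma``
    (natural-log parameters); abundance laws: ``fixed:N`` or
    ``uniform:lo,hi``.
    """

    seed: int
    genome_length: int = 100_000
    gc: float = 0.5
    n_bins: int = 200
    abundance_law: str = "fixed:20"
    read_length_law: str = "fixed:150"
    prefix_length: int = 50
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    position_ramp: Callable[[int], float] | None = None
    background_reads: int = 2_000
    errors_in_prefix: bool = False
    quality: int | None = None  # flat Phred score; None = FASTA (no quals)

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.5:
                raise ValueError(f"{name}={r} outside [0, 0.5]")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"gc={self.gc} outside [0, 1]")
        lo = _parse_abundance_law(self.abundance_law)(np.random.default_rng(0), 1).min()
        if lo < 2:
            raise ValueError(f"abundance law {self.abundance_law!r} can draw < 2")

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass
class TruthLog:
    """Injected-event ledger: one record per event plus denominators."""

    events: pd.DataFrame  # read_id, position, type, original, observed, planted
    planted_nonprefix_bases: int
    n_reads: int

    @property
    def planted_events(self) -> pd.DataFrame:
        return self.events[self.events["planted"]]

    @property
    def realized_total_rate(self) -> float:
        """Events per non-prefix template base over planted duplicate copies."""
        return len(self.planted_events) / self.planted_nonprefix_bases

    def realized_rate(self, kind: str) -> float:
        ev = self.planted_events
        return (ev["type"] == kind).sum() / self.planted_nonprefix_bases

    def to_tsv(self, path) -> None:
        self.events.to_csv(path, sep="\t", index=False)


def _parse_length_law(spec: str) -> Callable[[np.random.Generator, int], np.ndarray]:
    kind, _, args = spec.partition(":")
    if kind == "fixed":
        n = int(args)
        return lambda rng, size: np.full(size, n, dtype=np.int64)
    if kind == "lognormal":
        mu, sigma = (float(x) for x in args.split(","))
        return lambda rng, size: np.maximum(
            1, np.round(rng.lognormal(mu, sigma, size)).astype(np.int64)
        )
    raise ValueError(f"unknown length law {spec!r}")


def _parse_abundance_law(spec: str) -> Callable[[np.random.Generator, int], np.ndarray]:
    kind, _, args = spec.partition(":")
    if kind == "fixed":
        n = int(args)
        return lambda rng, size: np.full(size, n, dtype=np.int64)
    if kind == "uniform":
        lo, hi = (int(x) for x in args.split(","))
        return lambda rng, size: rng.integers(lo, hi + 1, size)
    raise ValueError(f"unknown abundance law {spec!r}")


def generate_template_genome(length: int, gc: float, seed: int) -> str:
    """I.i.d. template genome with P(G or C) = gc; reproducible by seed."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc={gc} outside [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A, C, G, T
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


def fragment_genome(
    genome: str,
    n_templates: int,
    read_length_law: str,
    seed: int,
) -> list[str]:
    """Draw template reads at uniform start positions with lengths from
    the law; draws longer than the genome are re-sampled (capped)."""
    law = _parse_length_law(read_length_law)
    rng = np.random.default_rng(seed)
    templates = []
    for _ in range(n_templates):
        for attempt in range(_MAX_FRAGMENT_RETRIES):
            length = int(law(rng, 1)[0])
            if length <= len(genome):
                break
        else:
            raise ValueError(
                f"read length law {read_length_law!r} keeps exceeding the "
                f"genome length {len(genome)}"
            )
        start = int(rng.integers(0, len(genome) - length + 1))
        templates.append(genome[start : start + length])
    return templates


def inject_errors(
    template: str,
    cfg: SimulationConfig,
    rng: np.random.Generator | int,
    position_offset: int = 0,
) -> tuple[str, list[dict]]:
    """Mutate a template with per-base substitution / deletion /
    insertion errors; every event is returned as a log record.

    Per base: delete with probability del_rate*ramp(p); otherwise
    substitute (uniform over the three other bases) with sub_rate*ramp(p);
    independently insert one uniform random base after it with
    ins_rate*ramp(p). Positions are logged 1-based on the template,
    shifted by ``position_offset`` (used when mutating only the
    non-prefix part of a read).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ramp = cfg.position_ramp
    out: list[str] = []
    events: list[dict] = []
    n = len(template)
    u = rng.random((n, 3))
    ins_choices = rng.integers(0, 4, n)
    sub_choices = rng.integers(0, 3, n)
    for i, base in enumerate(template):
        factor = ramp(i + position_offset) if ramp is not None else 1.0
        pos = position_offset + i + 1
        if u[i, 0] < cfg.del_rate * factor:
            events.append(
                {"position": pos, "type": "deletion", "original": base, "observed": "-"}
            )
        else:
            if u[i, 1] < cfg.sub_rate * factor:
                new = _OTHER[base][sub_choices[i]]
                events.append(
                    {"position": pos, "type": "substitution", "original": base, "observed": new}
                )
                out.append(new)
            else:
                out.append(base)
        if u[i, 2] < cfg.ins_rate * factor:
            ins = "ACGT"[ins_choices[i]]
            events.append(
                {"position": pos, "type": "insertion", "original": "-", "observed": ins}
            )
            out.append(ins)
    return "".join(out), events


def simulate_dataset(cfg: SimulationConfig) -> tuple[list[SequenceRead], TruthLog]:
    """Generate one dataset: planted prefix-identical ADR bins plus
    background singletons, in seeded-shuffled order, with a truth log."""
    rng = np.random.default_rng(cfg.seed)
    l = cfg.prefix_length
    genome = generate_template_genome(
        cfg.genome_length, cfg.gc, int(rng.integers(2**31))
    )
    bin_templates = fragment_genome(
        genome, cfg.n_bins, cfg.read_length_law, int(rng.integers(2**31))
    )
    abundances = _parse_abundance_law(cfg.abundance_law)(rng, cfg.n_bins)

    reads: list[SequenceRead] = []
    all_events: list[dict] = []
    planted_nonprefix_bases = 0

    for b, (template, abundance) in enumerate(zip(bin_templates, abundances)):
        if len(template) < l:
            raise ValueError(
                f"template read of length {len(template)} shorter than the "
                f"prefix length {l}; use a longer read length law"
            )
        for c in range(abundance):
            read_id = f"bin{b:05d}_r{c:04d}"
            if cfg.errors_in_prefix:
                bases, events = inject_errors(template, cfg, rng)
            else:
                suffix, events = inject_errors(template[l:], cfg, rng, position_offset=l)
                bases = template[:l] + suffix
            planted_nonprefix_bases += len(template) - l
            for ev in events:
                ev.update(read_id=read_id, planted=ev["position"] > l)
            all_events.extend(events)
            reads.append(_make_read(read_id, bases, cfg))

    bg_templates = fragment_genome(
        genome, cfg.background_reads, cfg.read_length_law, int(rng.integers(2**31))
    )
    for b, template in enumerate(bg_templates):
        read_id = f"bg{b:06d}"
        bases, events = inject_errors(template, cfg, rng)
        for ev in events:
            ev.update(read_id=read_id, planted=False)
        all_events.extend(events)
        reads.append(_make_read(read_id, bases, cfg))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    columns = ["read_id", "position", "type", "original", "observed", "planted"]
    events_frame = pd.DataFrame(all_events, columns=columns)
    truth = TruthLog(
        events=events_frame,
        planted_nonprefix_bases=planted_nonprefix_bases,
        n_reads=len(reads),
    )
    return reads, truth


def _make_read(read_id: str, bases: str, cfg: SimulationConfig) -> SequenceRead:
    quals = [cfg.quality] * len(bases) if cfg.quality is not None else None
    return SequenceRead(id=read_id, bases=bases, quals=quals)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


def evaluate_recovery(
    truth_rates: Sequence[float], estimates: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares of estimated on true error rates — the
    parameter-recovery check for the simulator/estimator pair."""
    if len(truth_rates) != len(estimates):
        raise ValueError("truth and estimate lists differ in length")
    if len(truth_rates) < 3:
        raise ValueError(f"need at least 3 paired points, got {len(truth_rates)}")
    fit = stats.linregress(truth_rates, estimates)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
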