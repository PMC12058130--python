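"""Synthetic binding-site datasets: motif-implanted positives, matched negatives.

Positives are i.i.d. background sequences (default GC 0.41, the human
genome average) carrying one instance sampled from a position weight
matrix, implanted at a uniformly random admissible offset.  Negatives are
length-matched background drawn at the empirical GC content of the
positives, or — to also preserve local composition — dinucleotide-
preserving shuffles of the positives.  Motif strength tunes the PWM's
sharpness and hence task difficulty; everything is reproducible from one
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DatasetManifest, LabeledSequence

__all__ = [
    "Pwm",
    "SimSpec",
    "random_pwm",
    "sample_background",
    "sample_motif",
    "dinucleotide_shuffle",
    "make_dataset",
    "gc_fraction",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Pwm:
    """Per-position nucleotide probabilities (columns over A,C,G,T)."""

    probabilities: np.ndarray  # (W, 4)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        object.__setattr__(self, "probabilities", p)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"PWM must be (W, 4), got {p.shape}")
        if (p < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if np.abs(p.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("PWM rows must each sum to 1")

    @property
    def width(self) -> int:
        return self.probabilities.shape[0]

    @property
    def information_content(self) -> np.ndarray:
        """Per-column information in bits relative to a uniform background."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / 0.25), 0.0)
        return terms.sum(axis=1)


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic dataset."""

    n_pos: int = 1000
    n_neg: int = 1000
    length: int = 200
    gc_content: float = 0.41
    motif: Pwm | None = None
    motif_width: int = 10
    motif_strength: float = 10.0
    implant_probability: float = 1.0
    negative_mode: str = "background"  # or 'dinucleotide_shuffle'
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be positive")
        ratio = self.n_pos / self.n_neg
        if not (3 / 7 - 1e-9 <= ratio <= 7 / 3 + 1e-9):
            raise ValueError(
                f"class ratio {ratio:.3f} outside the supported [3/7, 7/3]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly inside (0, 1)")
        if not 0.0 <= self.implant_probability <= 1.0:
            raise ValueError("implant_probability must lie in [0, 1]")
        if self.negative_mode not in ("background", "dinucleotide_shuffle"):
            raise ValueError(f"unknown negative_mode {self.negative_mode!r}")
        width = self.motif.width if self.motif is not None else self.motif_width
        if self.length < width:
            raise ValueError(
                f"length {self.length} shorter than motif width {width}")


def random_pwm(width: int, strength: float, seed: int) -> Pwm:
    """A random PWM whose sharpness grows with ``strength``.

    Each column starts from a Dirichlet(1,1,1,1) draw d and is mixed as

        column = ((1-t) * uniform + t * d + strength * onehot(argmax d))
                 / (1 + strength),   t = strength / (1 + strength)

    so strength 0 gives exactly uniform columns, intermediate strengths
    graded degenerate columns, and large strengths near-consensus columns
    (max probability at least strength / (1 + strength)).
    """
    if width < 4:
        raise ValueError(f"motif width must be at least 4, got {width}")
    if strength < 0:
        raise ValueError("strength must be non-negative")
    rng = np.random.default_rng(seed)
    d = rng.dirichlet(np.ones(4), size=width)  # (W, 4)
    t = strength / (1.0 + strength)
    onehot = np.zeros((width, 4))
    onehot[np.arange(width), d.argmax(axis=1)] = 1.0
    cols = ((1.0 - t) * 0.25 + t * d + strength * onehot) / (1.0 + strength)
    return Pwm(cols)


def sample_background(length: int, gc: float, rng: np.random.Generator) -> str:
    """i.i.d. bases with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly inside (0, 1)")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def sample_motif(pwm: Pwm, rng: np.random.Generator) -> str:
    """One motif instance drawn column-wise from the PWM."""
    idx = [rng.choice(4, p=col) for col in pwm.probabilities]
    return "".join(_BASES[idx])


def gc_fraction(bases: str) -> float:
    return (bases.count("G") + bases.count("C")) / len(bases)


def dinucleotide_shuffle(bases: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts.

    Chooses random last-exit edges forming an arborescence into the final
    base, then walks a random Eulerian path through the dinucleotide
    multigraph.
    """
    if len(bases) < 3:
        return bases
    vertices = sorted(set(bases))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(bases[:-1], bases[1:]):
        edges[a].append(b)
    last = bases[-1]
    while True:  # expected O(1) retries for DNA-sized alphabets
        last_exit = {v: rng.choice(edges[v]) for v in vertices
                     if v != last and edges[v]}
        # the chosen exits must lead every vertex into `last`
        ok = True
        for v in last_exit:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_exit.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_exit:
            rest.remove(last_exit[v])
        rng.shuffle(rest)
        if v in last_exit:
            rest.append(last_exit[v])
        shuffled[v] = rest
    out = [bases[0]]
    cur = bases[0]
    while shuffled[cur]:
        nxt = shuffled[cur].pop(0)
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_dataset(spec: SimSpec) -> DatasetManifest:
    """Generate the manifest described by ``spec``, seed-reproducibly.

    Positive ids record the implant offset (``|implant=-1`` when the
    label-noise control left a positive unimplanted); negative mean GC is
    matched to the positives within +/-0.01.
    """
    rng = np.random.default_rng(spec.seed)
    pwm = spec.motif if spec.motif is not None else random_pwm(
        spec.motif_width, spec.motif_strength, seed=spec.seed)
    L, W = spec.length, pwm.width

    positives = []
    for i in range(spec.n_pos):
        bases = sample_background(L, spec.gc_content, rng)
        pos = -1
        if rng.random() < spec.implant_probability:
            pos = int(rng.integers(0, L - W + 1))
            bases = bases[:pos] + sample_motif(pwm, rng) + bases[pos + W:]
        positives.append(LabeledSequence(
            id=f"pos_{i:06d}|implant={pos}", bases=bases, label=1))

    target_gc = float(np.mean([gc_fraction(s.bases) for s in positives]))
    if spec.negative_mode == "dinucleotide_shuffle":
        negatives = [LabeledSequence(
            id=f"neg_{i:06d}",
            bases=dinucleotide_shuffle(
                positives[int(rng.integers(0, spec.n_pos))].bases, rng),
            label=0) for i in range(spec.n_neg)]
    else:
        for _ in range(20):  # redraw until the GC-matching contract holds
            negatives = [LabeledSequence(
                id=f"neg_{i:06d}",
                bases=sample_background(L, target_gc, rng), label=0)
                for i in range(spec.n_neg)]
            neg_gc = float(np.mean([gc_fraction(s.bases) for s in negatives]))
            if abs(neg_gc - target_gc) <= 0.01:
                break
        else:
            raise RuntimeError("could not GC-match negatives within 0.01")
    return DatasetManifest(positives=positives, negatives=negatives,
                           source=f"simulated(seed={spec.seed})")
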