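"""Reading and writing the formats the tool touches.

FASTA sequence files (labels carried outside the format, since FASTA has no
label field), word2vec-style text embedding tables, flat YAML run configs,
and metric reports as JSON / one-row TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: every recognized flat-config key with its default; unknown keys are
#: rejected outright — a silently ignored hyperparameter typo is worse
#: than a hard failure.
CONFIG_SCHEMA: dict[str, object] = {
    # embedding
    "kmer_size": 3,
    "stride": 1,
    "embedding_dim": 100,
    "embedding_path": None,
    "embedding_trainable": False,
    "unk_policy": "zero",
    # architecture
    "conv_blocks": [1, 2, 3],
    "channel_multiplier": 1,
    "pool_width": 2,
    "use_bilstm": True,
    "bilstm_hidden": 128,
    "bilstm_combine": "concat",
    "bilstm_peephole": True,
    "residual": True,
    "head": "kan",
    "fusion_dim": 128,
    "kan_hidden": 32,
    "kan_grid_size": 5,
    "kan_degree": 3,
    "kan_use_base": True,
    "dropout_rate": 0.3,
    "norm": "layer_norm",
    "sequence_length": 200,
    # training
    "learning_rate": 5e-4,
    "batch_size": 64,
    "max_epochs": 20,
    "early_stop_batches": 5000,
    "eval_every": 100,
    "threshold": 0.5,
    "val_fraction": 0.10,
    "test_fraction": 0.10,
    # simulation
    "n_pos": 1000,
    "n_neg": 1000,
    "gc_content": 0.41,
    "motif_width": 10,
    "motif_strength": 10.0,
    "implant_probability": 1.0,
    "negative_mode": "background",
    # run control
    "seed": 0,
}


@dataclass(frozen=True)
class LabeledSequence:
    """A fixed-length DNA sequence with a binary binding-site label."""

    id: str
    bases: str
    label: int

    def __post_init__(self):
        if not self.bases:
            raise ValueError(f"sequence {self.id!r}: empty bases")
        bad = set(self.bases) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {sorted(bad)}")
        if self.label not in (0, 1):
            raise ValueError(f"sequence {self.id!r}: label must be 0 or 1")

    def __len__(self):
        return len(self.bases)


@dataclass
class DatasetManifest:
    """Positive and negative sequence sets with a recorded class ratio.

    The positive:negative ratio must stay within [3/7, 7/3], mirroring the
    balance range of the ChIP-seq benchmark collections this tool targets.
    """

    positives: list[LabeledSequence]
    negatives: list[LabeledSequence]
    source: str = ""

    def __post_init__(self):
        if any(s.label != 1 for s in self.positives):
            raise ValueError("positives list contains a label-0 sequence")
        if any(s.label != 0 for s in self.negatives):
            raise ValueError("negatives list contains a label-1 sequence")
        if not self.positives or not self.negatives:
            raise ValueError("both classes must be non-empty")
        r = self.class_ratio
        if not (3 / 7 - 1e-9 <= r <= 7 / 3 + 1e-9):
            raise ValueError(
                f"positive:negative ratio {r:.3f} outside [3/7, 7/3]")

    @property
    def class_ratio(self) -> float:
        return len(self.positives) / len(self.negatives)

    @property
    def sequences(self) -> list[LabeledSequence]:
        return self.positives + self.negatives

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.sequences], dtype=np.int64)


@dataclass
class EmbeddingTable:
    """k-mer token -> dense vector map (word2vec-text compatible)."""

    dimension: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    unk_policy: str = "zero"

    def __post_init__(self):
        if self.unk_policy not in ("zero", "learned"):
            raise ValueError(f"unk_policy must be 'zero' or 'learned', "
                             f"got {self.unk_policy!r}")
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {tok!r} has length {vec.shape}, "
                    f"expected ({self.dimension},)")

    def lookup(self, token: str) -> np.ndarray | None:
        return self.vectors.get(token.upper())

    def __len__(self):
        return len(self.vectors)


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


def read_fasta(path: str | Path, label: int) -> list[LabeledSequence]:
    """Parse a FASTA file, applying ``label`` to every record.

    Bases are uppercased; anything outside {A,C,G,T,N} is a parse error
    reported with its line number.  Parsing is done directly (rather than
    through a lenient library parser) so that errors can name lines.
    """
    path = Path(path)
    records: list[LabeledSequence] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []

    def flush():
        if header is None:
            return
        bases = "".join(parts)
        if not bases:
            raise FastaParseError(
                f"{path}:{header_line}: record {header!r} has no sequence")
        records.append(LabeledSequence(id=header, bases=bases, label=label))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty record header")
                header_line = lineno
                parts = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header")
                up = line.upper()
                bad = set(up) - DNA_ALPHABET
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: invalid characters {sorted(bad)}")
                parts.append(up)
    flush()
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: list[LabeledSequence], path: str | Path) -> None:
    """Write sequences as FASTA; duplicate ids get a numeric suffix."""
    if not seqs:
        raise ValueError("refusing to write an empty dataset")
    seen: dict[str, int] = {}
    records = []
    for s in seqs:
        name = s.id
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicate id %r renamed to %r", name, new)
            name = new
        else:
            seen[name] = 0
        records.append(SeqRecord(Seq(s.bases), id=name, description=""))
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


def read_word2vec_text(path: str | Path) -> EmbeddingTable:
    """Read a word2vec text file: header ``V D`` then ``token v1 .. vD`` rows."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header 'V D', got {header}")
        vocab, dim = int(header[0]), int(header[1])
        vectors: dict[str, np.ndarray] = {}
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.split()
            token = fields[0].upper()
            vec = np.array(fields[1:], dtype=np.float64)
            if vec.shape[0] != dim:
                raise ValueError(
                    f"{path}:{lineno}: token {token!r} has {vec.shape[0]} "
                    f"values, expected {dim}")
            if token in vectors:
                raise ValueError(f"{path}:{lineno}: duplicate token {token!r}")
            vectors[token] = vec
    if len(vectors) != vocab:
        raise ValueError(
            f"{path}: header declares {vocab} tokens but file has {len(vectors)}")
    return EmbeddingTable(dimension=dim, vectors=vectors)


def write_word2vec_text(table: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(repr(float(v)) for v in vec) + "\n")


# -- run configuration --------------------------------------------------------

def validate_config(overrides: dict) -> dict:
    """Merge ``overrides`` into the defaults; unknown keys are an error."""
    unknown = set(overrides) - set(CONFIG_SCHEMA)
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(CONFIG_SCHEMA)
    merged.update(overrides)
    return merged


def load_config(path: str | Path) -> dict:
    """Load a flat YAML config and validate it against the schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    return validate_config(raw)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


# -- metric reports -----------------------------------------------------------

METRIC_KEYS = ("roc_auc", "pr_auc", "precision", "recall", "accuracy", "f1", "mcc")


def write_metrics_json(report: dict, path: str | Path) -> None:
    missing = [k for k in METRIC_KEYS if k not in report]
    if missing:
        raise KeyError(f"report missing metric keys: {missing}")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_metrics_tsv(report: dict, path: str | Path, run_id: str = "run") -> None:
    """One header line + one data row, for aggregation across runs."""
    cols = ["run_id", *METRIC_KEYS]
    vals = [run_id] + [f"{float(report[k]):.6f}" for k in METRIC_KEYS]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fh.write("\t".join(vals) + "\n")
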