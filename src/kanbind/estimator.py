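"""scikit-learn style estimator wrapping the full pipeline.

`CbrKanClassifier` takes raw fixed-length DNA strings as samples, handles
k-mer tokenization and embedding internally, carves a stratified
validation split out of the training data for early stopping, and exposes
the usual ``fit`` / ``predict`` / ``predict_proba`` surface so it composes
with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from .io_formats import EmbeddingTable, LabeledSequence
from .model import ModelConfig, build_model
from .train_eval import TrainConfig, train

__all__ = ["CbrKanClassifier"]


class CbrKanClassifier(BaseEstimator, ClassifierMixin):
    """Binding-site classifier: multi-scale CNN + BiLSTM + residual + KAN head.

    Parameters mirror the architecture and training knobs; every ablation
    variant of the network is reachable through them.  ``X`` is a sequence
    of equal-length DNA strings (or :class:`LabeledSequence`), ``y`` binary
    labels.

    Attributes (after fit)
    ----------------------
    model_ : the trained network
    history_ : list of per-evaluation dicts (batch, epoch, loss, val AUC)
    classes_ : array([0, 1])
    sequence_length_ : the common input length L
    n_parameters_ : trainable parameter count
    """

    def __init__(self, conv_blocks=(1, 2, 3), channel_multiplier=1,
                 pool_width=2, use_bilstm=True, bilstm_hidden=128,
                 bilstm_combine="concat", bilstm_peephole=True, residual=True,
                 head="kan", fusion_dim=128, kan_hidden=32, kan_grid_size=5,
                 kan_degree=3, kan_use_base=True, dropout_rate=0.3,
                 norm="layer_norm", kmer_size=3, stride=1, embedding_dim=100,
                 embedding_mode="pretrained", embedding_table=None,
                 learning_rate=5e-4, batch_size=64, max_epochs=20,
                 early_stop_batches=5000, eval_every=100, val_fraction=0.1,
                 random_state=0):
        self.conv_blocks = conv_blocks
        self.channel_multiplier = channel_multiplier
        self.pool_width = pool_width
        self.use_bilstm = use_bilstm
        self.bilstm_hidden = bilstm_hidden
        self.bilstm_combine = bilstm_combine
        self.bilstm_peephole = bilstm_peephole
        self.residual = residual
        self.head = head
        self.fusion_dim = fusion_dim
        self.kan_hidden = kan_hidden
        self.kan_grid_size = kan_grid_size
        self.kan_degree = kan_degree
        self.kan_use_base = kan_use_base
        self.dropout_rate = dropout_rate
        self.norm = norm
        self.kmer_size = kmer_size
        self.stride = stride
        self.embedding_dim = embedding_dim
        self.embedding_mode = embedding_mode
        self.embedding_table = embedding_table
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_batches = early_stop_batches
        self.eval_every = eval_every
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- internals -----------------------------------------------------------
    def _as_sequences(self, X, y=None) -> list[LabeledSequence]:
        labels = np.zeros(len(X), dtype=int) if y is None else np.asarray(y)
        seqs = []
        for i, (x, lab) in enumerate(zip(X, labels)):
            if isinstance(x, LabeledSequence):
                seqs.append(LabeledSequence(x.id, x.bases, int(lab)))
            else:
                seqs.append(LabeledSequence(f"seq_{i:06d}", str(x).upper(),
                                            int(lab)))
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        return seqs

    def _model_config(self, length: int) -> ModelConfig:
        return ModelConfig(
            conv_blocks=tuple(self.conv_blocks),
            channel_multiplier=self.channel_multiplier,
            pool_width=self.pool_width, use_bilstm=self.use_bilstm,
            bilstm_hidden=self.bilstm_hidden,
            bilstm_combine=self.bilstm_combine,
            bilstm_peephole=self.bilstm_peephole, residual=self.residual,
            head=self.head, fusion_dim=self.fusion_dim,
            kan_hidden=self.kan_hidden, kan_grid_size=self.kan_grid_size,
            kan_degree=self.kan_degree, kan_use_base=self.kan_use_base,
            dropout_rate=self.dropout_rate, norm=self.norm,
            kmer_size=self.kmer_size, stride=self.stride,
            embedding_dim=self.embedding_dim,
            embedding_mode=self.embedding_mode, sequence_length=length)

    # -- sklearn surface ------------------------------------------------------
    def fit(self, X, y):
        y = np.asarray(y)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        seqs = self._as_sequences(X, y)
        self.sequence_length_ = len(seqs[0])
        self.classes_ = np.array([0, 1])
        tr, val = train_test_split(seqs, test_size=self.val_fraction,
                                   stratify=[s.label for s in seqs],
                                   random_state=self.random_state)
        table: EmbeddingTable | None = self.embedding_table
        model = build_model(self._model_config(self.sequence_length_),
                            seed=self.random_state, table=table)
        tconf = TrainConfig(learning_rate=self.learning_rate,
                            batch_size=self.batch_size,
                            max_epochs=self.max_epochs,
                            early_stop_batches=self.early_stop_batches,
                            eval_every=self.eval_every,
                            seed=self.random_state)
        self.model_, self.history_ = train(model, tr, val, tconf)
        self.n_parameters_ = self.model_.num_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        from .embedding import TokenizerSpec, encode_indices
        seqs = self._as_sequences(X)
        if len(seqs[0]) != self.sequence_length_:
            raise ValueError(
                f"sequences of length {len(seqs[0])} do not match the "
                f"trained length {self.sequence_length_}")
        idx = encode_indices(seqs, TokenizerSpec(self.kmer_size, self.stride))
        p1 = self.model_.predict_proba(idx)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("this CbrKanClassifier is not fitted yet")

    def _more_tags(self):  # sequences, not numeric matrices
        return {"X_types": ["string"], "non_deterministic": False}
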