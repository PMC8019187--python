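"""Training configuration using the hyperparameter names of the original
DBM fitting interface (the names a user of the tool knows: ``learningrate``,
``epochspretraining``, ``nhiddens``, ...).  The Python estimators use PEP8
spellings; this dataclass is the bridge used by the CLI and config files.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TrainConfig:
    epochs: int = 30
    epochspretraining: int = 30
    learningrate: float = 0.1
    learningratepretraining: float = 0.001
    nhiddens: tuple = (50, 10)
    batchsizepretraining: int = 20
    batchsize: int = 20
    cdsteps: int = 1
    seed: int = 0

    def __post_init__(self):
        self.nhiddens = tuple(int(h) for h in self.nhiddens)
        if self.epochs < 0 or self.epochspretraining < 1:
            raise ValueError("epoch counts must be >= 1 (fine-tuning may be 0)")
        if self.learningrate <= 0 or self.learningratepretraining <= 0:
            raise ValueError("learning rates must be positive")
        if self.batchsize < 1 or self.batchsizepretraining < 1 or self.cdsteps < 1:
            raise ValueError("batch sizes and cdsteps must be >= 1")
        if any(h < 1 for h in self.nhiddens):
            raise ValueError("every hidden layer needs at least one unit")

    def rbm_params(self) -> dict:
        """Estimator kwargs for a single RBM (pre-training settings apply)."""
        return dict(n_hidden=self.nhiddens[0], epochs=self.epochspretraining,
                    learning_rate=self.learningratepretraining,
                    batch_size=self.batchsizepretraining, cd_steps=self.cdsteps,
                    random_state=self.seed)

    def dbm_params(self) -> dict:
        return dict(n_hiddens=self.nhiddens, epochs=self.epochs,
                    learning_rate=self.learningrate,
                    epochs_pretraining=self.epochspretraining,
                    learning_rate_pretraining=self.learningratepretraining,
                    batch_size_pretraining=self.batchsizepretraining,
                    batch_size=self.batchsize, cd_steps=self.cdsteps,
                    random_state=self.seed)
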