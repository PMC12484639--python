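import dataclasses

from ecgscar.pipeline import PipelineConfig
from ecgscar.scarf import ScarfConfig
from ecgscar.synthetic import CohortConfig


def quick_scarf(**overrides) -> ScarfConfig:
    """A fast ScarfConfig for unit tests (small nets, few epochs)."""
    base = dict(
        embedding_dim=16,
        encoder_hidden=(64,),
        head_hidden=(16,),
        pretrain_epochs=8,
        finetune_epochs=25,
        batch_size=64,
        seed=0,
    )
    base.update(overrides)
    return ScarfConfig(**base)


def quick_pipeline_config(seed: int = 0, n_patients: int = 150) -> PipelineConfig:
    """A fast whole-pipeline config for unit tests."""
    cfg = PipelineConfig(cohort=CohortConfig(n_patients=n_patients))
    cfg = dataclasses.replace(cfg, scarf=quick_scarf())
    return cfg.with_seed(seed)
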