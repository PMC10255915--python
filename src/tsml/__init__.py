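"""Two-stream mutual-learning video behavior classification.

An appearance (RGB) stream and a motion (optical-flow) stream each train
two peer student networks by deep mutual learning — cross-entropy plus a
KL-divergence term toward the peer's posterior — and the two streams'
class probabilities are fused late by a convex combination.  A seeded
synthetic clip generator provides a benchmark whose classes are only
jointly separable by appearance and motion, so the value of fusion and
of mutual learning is measurable end to end on a CPU.
"""

from .backbones import (BackboneSpec, build_backbone, count_flops, count_params,
                        register_backbone, registry_names)
from .data import (ClipRecord, DatasetManifest, IOConfig, VideoSample,
                   compute_flow, load_sample, load_split_arrays, sample_frames,
                   sample_indices, scan_dataset, split_per_class)
from .errors import ConfigurationError, InvalidInputError, TSMLError
from .evaluation import (EvalReport, FusionConfig, evaluate, evaluate_all, fuse,
                         results_table)
from .experiments import (ExperimentCell, model_label, run_benchmark,
                          run_experiment_matrix)
from .losses import (LossBreakdown, StudentLoss, cross_entropy, kl_divergence,
                     mutual_stream_loss, softmax_probs, stream_loss,
                     student_loss)
from .model import (StreamPair, StudentOutput, TSMLModel, forward_stream,
                    load_stream_pair, save_stream_pair)
from .synthetic import (ClassSignature, GeneratorConfig, default_signatures,
                        generate_clip, generate_dataset, make_benchmark_data)
from .train import TrainConfig, TrainLog, train_single, train_stream, train_tsml

__version__ = "0.1.0"

__all__ = [
    "BackboneSpec", "build_backbone", "count_flops", "count_params",
    "register_backbone", "registry_names",
    "ClipRecord", "DatasetManifest", "IOConfig", "VideoSample", "compute_flow",
    "load_sample", "load_split_arrays", "sample_frames", "sample_indices",
    "scan_dataset", "split_per_class",
    "ConfigurationError", "InvalidInputError", "TSMLError",
    "EvalReport", "FusionConfig", "evaluate", "evaluate_all", "fuse",
    "results_table",
    "ExperimentCell", "model_label", "run_benchmark", "run_experiment_matrix",
    "LossBreakdown", "StudentLoss", "cross_entropy", "kl_divergence",
    "mutual_stream_loss", "softmax_probs", "stream_loss", "student_loss",
    "StreamPair", "StudentOutput", "TSMLModel", "forward_stream",
    "load_stream_pair", "save_stream_pair",
    "ClassSignature", "GeneratorConfig", "default_signatures", "generate_clip",
    "generate_dataset", "make_benchmark_data",
    "TrainConfig", "TrainLog", "train_single", "train_stream", "train_tsml",
]
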