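"""wave2vec: encoding-based classification of real-valued time series.

Signals are converted to symbol sequences (delta encoding + Gaussian
quantization), symbols are embedded with CBOW, classes are modeled by
vector summation, and sequences are classified by cosine similarity to the
class models.  See the module docstrings for the science of each stage.
"""

from .classifier import (
    ClassModel,
    PatternStats,
    SequenceVector,
    build_class_model,
    classify,
    classify_by_patterns,
    cosine_similarity,
    fit_pattern_stats,
    sequence_class_prob,
    sequence_vector,
)
from .embedding import (
    CBOWConfig,
    Vocabulary,
    WaveVectorTable,
    build_vocab,
    make_training_windows,
    train_cbow,
)
from .encoder import (
    EncoderConfig,
    QuantizerSpec,
    decode,
    delta_encode,
    downsample,
    encode_signal,
    fit_quantizer,
    quantize,
    quantize_amplitude,
)
from .errors import Wave2vecError
from .evaluation import (
    DEFAULT_BASE_N_LIST,
    EvalReport,
    FoldCounts,
    kfold_split,
    metrics,
    run_cv,
    sweep_base_n,
)
from .signal_io import (
    SignalDialect,
    read_dataset,
    read_instance_file,
    read_labels_manifest,
    read_symbol_corpus,
    read_vector_table,
    write_labels_manifest,
    write_symbol_corpus,
    write_vector_table,
)
from .synthgen import (
    Motif,
    SynthConfig,
    default_config,
    generate_dataset,
    generate_instance,
    motif_expected_tokens,
    planted_symbols,
)
from .types import DeltaSeries, LabeledDataset, RawSignal, SymbolSequence
from .viz import (
    SimilarityMatrix,
    matrix_difference,
    render_heatmap,
    similarity_matrix,
    top_divergent_pairs,
    write_matrix_tsv,
)

__version__ = "0.1.0"
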