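"""pvpkit: phage virion protein identification and functional annotation.

Pipeline: protein (or ORF) sequences -> per-protein embeddings (mean-pooled
residue vectors from a protein language model, or a deterministic offline
backend) -> a small 1-D CNN trained with an asymmetric loss that counters
class imbalance -> two-stage annotation (virion / non-virion, then one of
seven functional categories), with homology-, time- and imbalance-aware
benchmark splitting.
"""

from .asl import ASLConfig, asl_loss, asymmetric_weight, log_softmax, softmax
from .classifier import (
    ClassifierConfig,
    ModelState,
    build_model,
    conv_out_len,
    forward,
    load_model,
    save_model,
    shape_chain,
)
from .core_io import (
    NON_PVP,
    PVP,
    UNLABELED,
    FunctionalCategory,
    LabelRuleSet,
    PredictionRecord,
    ProteinRecord,
    label_record,
    label_records,
    read_fasta,
    translate_cds,
    write_fasta,
    write_predictions_tsv,
)
from .embeddings import (
    EmbeddingTable,
    KmerHashBackend,
    embed_proteins,
    kmer_hash_backend,
    load_table,
    mean_pool,
    save_table,
)
from .splits import (
    DatasetSplit,
    SimilarityScore,
    pairwise_similarity,
    split_by_imbalance,
    split_by_similarity,
    split_by_time,
    symmetric_score,
)
from .train_eval import (
    ClassifierResults,
    ClassPrediction,
    MetricsReport,
    TrainConfig,
    VirionClassifier,
    compute_metrics,
    gamma_sweep,
    predict,
    train,
)
from .annotate import (
    ORF,
    AnnotationResult,
    annotate_genome,
    annotate_proteins,
    filter_by_category,
    write_gff3,
)
from .synthetic import (
    FamilySpec,
    GaussianSpec,
    gen_annotation_corpus,
    gen_gaussian_embeddings,
    gen_protein_families,
)

__version__ = "0.1.0"
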