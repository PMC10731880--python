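"""grelex — sentence-graph relation extraction.

Sentences are modelled as graphs over word-piece tokens derived from
dependency parses; a graph pointer layer samples, ranks, and aggregates
multi-hop neighbors of every token on top of contextual embeddings; a
fusion head classifies the marked entity pair's relation; evaluation is
micro-averaged over the positive relation classes.
"""

from importlib import resources

from .corpus_io import (BINARY_SCHEME, CHEMPROT_SCHEME, LabelScheme, Mention,
                        RelationInstance, expand_pairs, map_label,
                        mark_entities, read_instances, write_instances)
from .parse_graph import (DependencyParse, SentenceGraph, WordPieceAlignment,
                          align_wordpieces, build_sentence_graph,
                          graph_distance, read_conllu, write_conllu)
from .sampler import (NeighborSequence, SamplerConfig, batch_sample,
                      sample_neighbor_sequence, two_hop_coverage)
from .gpnn import (GpnnConfig, aggregate_selected, encode_neighbors,
                   gcn_forward, gpnn_layer, init_gpnn_params, pointer_decode)
from .encoder import EncodedSentence, PretrainedEncoder, ToyEncoder
from .model import (HeadConfig, RelationModel, TrainConfig, classify,
                    fuse_features, prepare_instances, sentence_representation)
from .evaluation import (ConfusionMatrix, EvalReport, build_report,
                         confusion_matrix, micro_metrics, per_class_metrics,
                         read_matrix_tsv, write_matrix_tsv)
from .synthetic import (SyntheticCorpus, SyntheticSpec, generate_corpus,
                        generate_random_tree, topological_label,
                        trigger_majority_accuracy)

__version__ = "0.1.0"


def chemprot_test_matrix() -> ConfusionMatrix:
    """The published CHEMPROT test-set confusion matrix shipped with the
    package (rows = predictions, columns = gold)."""
    ref = resources.files("grelex").joinpath("data/chemprot_test_confusion.tsv")
    with resources.as_file(ref) as path:
        return read_matrix_tsv(path)
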