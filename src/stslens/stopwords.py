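"""Built-in English stop-word list (version 1).

The quantitative error analysis removes stop words before computing the
frequency-based pair features.  The list is deliberately small and
versioned so feature tables are reproducible across package releases;
pass your own set to ``compute_pair_features`` to override it.
"""

STOPWORDS_V1: frozenset[str] = frozenset(
    {
        "the", "and", "of", "to", "in", "for", "with", "on", "at", "by",
        "as", "is", "was", "were", "be", "a", "an", "it", "that", "this",
        "or", "from", "no", "not", "any",
    }
)

DEFAULT_STOPWORDS = STOPWORDS_V1
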