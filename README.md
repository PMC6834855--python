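# kmertune

Reference-free tuning of k-mer error-correction parameters for NGS short
reads, using language-model perplexity as the quality signal.

## The problem

k-spectrum error correctors (and their relatives) hinge on one
configuration parameter — the k-mer size k, or a genome-length parameter in
some tools — and the best value changes with the dataset *and* the tool.
The usual way to pick it is a brute-force sweep scored against a reference
genome (alignment rate, error-correction gain), which is unavailable for
*de novo* work and expensive even when a reference exists.

`kmertune` replaces the reference with a language model trained on the
uncorrected reads themselves.  Reads are treated as text: a word n-gram
model over `L_s`-base segments (default trigram over 7-mers), or a
character-level tanh RNN.  Because correct sequence vastly outnumbers any
particular error at usual coverage, well-corrected reads look like text the
model has seen many times, and badly-corrected reads do not.  The corpus
perplexity of a corrected sample,

    PP = exp( -(1/m) * sum_i log P(W_i | W_{i-1}, ..., W_{i-n}) ),

is therefore anti-correlated with correction quality, and

    k_opt = argmin_k PP( LM, correct(sample, k) )

is found with a memoized hill climb over the parameter grid: evaluate k and
its δ-neighbors, move to the strictly better neighbor, stop at a local
minimum; multiple starts share one evaluation cache.  Correction runs on a
coverage-targeted subsample (Lander–Waterman sizing, ≥30X) rather than the
full dataset.

The package also ships the pieces needed to validate this hermetically: a
read simulator with per-read ground truth, three synthetic error models
(deletion / insertion / substitution, plus an equiprobable mixture, at low
U{1..5} and high U{6..10} errors per read), a built-in substitution-only
k-spectrum corrector, an adapter for external corrector executables, and
truth-based metrics (base accuracy, EC gain).

## Worked example

```bash
# 50X of 100 bp reads from a 100 kb random genome, 2% substitution errors
kmertune simulate --genome-length 100000 --coverage 50 --read-length 100 \
    --sub-rate 0.02 --seed 1 --out reads.fastq --truth truth.tsv

# tune k for the built-in corrector, then correct everything at the best k
kmertune tune --reads reads.fastq --lm ngram --min-k 10 --max-k 30 \
    --genome-length 100000 --seed 1 --out corrected.fastq --report report.json

# score the result against the simulated truth
kmertune evaluate --original reads.fastq --corrected corrected.fastq \
    --truth truth.tsv
```

The tune step prints, for this input:

```
selected k = 22 (5 evaluations); corrected reads at corrected.fastq
```

i.e. the hill climb scored 5 of the 21 candidate k values before stopping
(`report.json` holds the full perplexity-by-k map and the walk trace), and
the evaluate step reports

```
{
  "base_accuracy": 0.9947338,
  "errors_before": 99861,
  "errors_after": 26331,
  "errors_removed": 73533,
  "errors_introduced": 3,
  "ec_gain": 0.7363234896506143
}
```

— about 74% of the injected errors are removed net of the 3 the corrector
introduced, and per-base accuracy rises from 0.980 to 0.995.  The same
workflow applies to an external tool by declaring its command template
(`ECToolSpec` / `run_external_ec`) instead of the built-in corrector.

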