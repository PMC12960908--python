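# ssm6ma

A multi-scale, position-specific selective state-space classifier for DNA
N6-methyladenine (6mA) site prediction, with a synthetic planted-motif
benchmark, a full training/evaluation harness, architecture ablations, and
interpretation utilities.

## The problem

6mA is an epigenetic mark on adenine. The standard prediction task takes a
41-bp DNA window centered on an adenine and asks whether that central
adenine is methylated. Benchmarks supply balanced FASTA pairs (methylated
positives, unmethylated negatives); useful signal is short, local, and —
critically — *position-anchored*: for example guanine is strongly enriched
immediately up- and downstream of true 6mA sites (a GAG core at window
positions 20–22, 1-based, center 21).

## The model

Each nucleotide is embedded into N dimensions, giving `X ∈ R^{L×N}`. Three
parallel branches (window sizes K = 3, 5, 7), each a stack of six layers,
extract multi-scale features. One layer computes

```
D = X·W_in                         linear, R^{L×M}
g_{i,p} = Σ_k Σ_j f^{(K)}_{i,p,k,j} · d_{i−⌊K/2⌋+k−1, j}     (zero-padded)
G' = SiLU(G)
h_t = Ā_t ⊙ h_{t−1} + B̄_t · g'_t ;  z_t = ⟨C_t, h_t⟩        selective SSM
out = X + LayerNorm(Z)·W_out                                  residual
```

The convolution is *position-specific*: every window position i has its own
filter weights, so positional identity lives in the parameters. The state
recurrence is *selective*: B_t, C_t and the step size Δ_t are functions of
the current input, with zero-order-hold discretization Ā_t = exp(Δ_t·A),
B̄_t = Δ_t·B_t and a trainable negative-diagonal A. The three branch
outputs Z3, Z5, Z7 are fused per cell by softmax-normalized learnable
query weights (a convex combination), and a 384→16→1 fully connected head
with ReLU, dropout 0.2 and a sigmoid emits the methylation probability.

Evaluation reports ACC, SN, SP, MCC and AUC; training uses Adam (batch 64,
learning rate chosen by dataset size), 5-fold stratified cross-validation
and early stopping on validation accuracy (patience 30).

The network, including its gradients, is implemented in NumPy with a small
tape-based autodiff engine (`ssm6ma.autodiff`) and numba-compiled scan
kernels; there is no deep-learning-framework dependency.

## Worked example

```python
from ssm6ma import (GeneratorConfig, ModelConfig, cross_validate,
                    generate_dataset)
from ssm6ma.training import TrainConfig

train = generate_dataset(GeneratorConfig(n_per_class=2000, seed=101))
test = generate_dataset(GeneratorConfig(n_per_class=1000, seed=202))
report = cross_validate(train, test, ModelConfig(dtype="float32"),
                        TrainConfig(learning_rate_small=1e-3, patience=1,
                                    max_epochs=3, folds=5, seed=0))
print(report.per_fold.round(4).to_string(index=False))
print(report.mean.round(4).to_string())
```

prints (fold models trained on the default generator: GAG planted at
anchor 20 in 90% of positives and 10% of negatives):

```
 fold    ACC    SN    SP    MCC    AUC
    0 0.8735 0.902 0.845 0.7482 0.8666
    1 0.8735 0.902 0.845 0.7482 0.8731
    2 0.8735 0.902 0.845 0.7482 0.8742
    3 0.8735 0.902 0.845 0.7482 0.8792
    4 0.8735 0.902 0.845 0.7482 0.8730
ACC    0.8735
MCC    0.7482
SN     0.9020
SP     0.8450
AUC    0.8732
```

The held-out MCC ≈ 0.748 matches the generator's likelihood-ratio-optimal
rule ("positive iff G at 20 and G at 22", accuracy 0.875 and MCC ≈ 0.75 at
these planting rates): every fold model has recovered the planted signal
up to the Bayes limit, which is why their thresholded metrics coincide
exactly while AUC still varies with the fold's soft scores. The CLI (`ssm6ma simulate|train|evaluate|
predict|ablate|interpret`) exposes the same pipeline from the shell.

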