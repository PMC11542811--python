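# plastinet

Energy accounting for synaptic plasticity in feedforward network training,
plus the plasticity-restriction rules that reduce it.

A two-layer perceptron (leaky-ReLU hidden units, linear outputs, MSE) is
trained by per-sample SGD to a validation-accuracy criterion while an energy
ledger charges every applied weight change:

* **M0** — the number of nonzero synaptic updates (consolidation events under
  two-compartment plasticity);
* **M1** — the accumulated absolute weight change, `sum |dw|`;
* arbitrary `sum |dw|^alpha` accumulators in between.

On top of the plain training loop the package implements:

* **Restriction strategies** (`plastinet.strategies`): dropconnect,
  fixed Bernoulli synapse masks, fixed hidden-neuron masks, coordinated
  plastic *subnets* (incoming and outgoing synapses of a fixed subset of
  hidden units), and competitive *top-k* selection of the largest-magnitude
  updates (per layer, per neuron, or within a subnet).
* **Synaptic caching** (`plastinet.caching`): updates accumulate in a cheap
  decaying transient weight component and are consolidated into a persistent
  component when a threshold is crossed.
* **Mask theory** (`plastinet.theory`): the closed-form optimal mask
  densities `(f0*, f1*)` that minimize the expected plastic-synapse count
  subject to a fixed number of plastic input→hidden→output paths, with a
  brute-force grid-search oracle.
* **Scaling analysis** (`plastinet.experiments`): criterion training runs,
  log-log power-law fits, extrapolation of fitted exponents to biological
  synapse counts, and the inverse Simpson index `q = 1/(N sum p_i^2)` of
  per-synapse update probabilities.
* **Datasets** (`plastinet.datasets`): an IDX reader for MNIST/fashionMNIST,
  per-feature zero-meaning (training means reused on held-out sets), and a
  synthetic prototype-plus-noise generator so everything is testable offline.

## CLI

```sh
plastinet train --hidden 100 --seed 1                  # one criterion run (synthetic data)
plastinet train --mnist-dir data/mnist --hidden 1000 \
    --variant topk --topk-fraction 0.01               # competitive updating on MNIST
plastinet sweep sweep.yaml --out runs.csv              # size x lr x strategy grid
plastinet report runs.csv                              # per-size means + fitted exponents
plastinet theory --sizes 100,1000,10000                # optimal-mask table
plastinet extrapolate --exponent 0.43                  # fold-increase at 3e11 synapses
plastinet q-index counts.txt                           # inverse Simpson index
```

A sweep config is a small YAML file:

```yaml
sizes: [100, 300, 1000]
learning_rates: [0.01]
seeds: [0, 1, 2]
mnist_dir: data/mnist   # omit to use synthetic data
strategy: {variant: subnet, subnet_size: 60}
caching: {theta: 0.05, lambda_decay: 0.001, c: 0.01}
```

## MNIST data

The empirical scaling numbers need the original MNIST IDX files, which are
not redistributed here. Place the four files (`train-images-idx3-ubyte`,
`train-labels-idx1-ubyte`, `t10k-images-idx3-ubyte`, `t10k-labels-idx1-ubyte`,
plain or `.gz`) under `data/mnist/`, e.g.:

```sh
mkdir -p data/mnist && cd data/mnist
for f in train-images-idx3-ubyte train-labels-idx1-ubyte \
         t10k-images-idx3-ubyte t10k-labels-idx1-ubyte; do
  curl -LO https://ossci-datasets.s3.amazonaws.com/mnist/$f.gz
done
```

Without the files, the MNIST-dependent acceptance test fails with a
diagnostic and the acceptance report omits the empirical targets; all
analytic and synthetic-data checks run regardless.

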