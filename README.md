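# hybkit

Round-trip conversion of kinetic systems-biology models between **SBML**
and the text-based **HMOD** format, and compilation of feedforward
neural networks into standard SBML constructs — producing
SBML-encodable **hybrid semiparametric models** whose behaviour any
SBML-aware simulator can reproduce.

## The problem

Mechanistic kinetic models — material balances over biochemical species,

dS_i/dt = (1/V) Σ_j ν_ij · v_j(S, p),

with rate laws v_j such as mass action (k·S) or Michaelis–Menten
(V_max·S/(K_m+S)) — are abundant in databases like BioModels, encoded in
SBML.  Hybrid semiparametric modelling replaces poorly understood rate
laws with data-driven components, typically a feedforward artificial
neural network (ANN): inputs x are min–max scaled to x̂ ∈ [0,1]^n, each
layer computes h = σ(W·h_prev + b) with σ = tanh (linear on the output
layer), and output k drives reaction rate v_k.  SBML has no native ANN
concept, which locks hybrid models out of the standard tool ecosystem.

`hybkit` closes that gap for modellers who want hybrid models to live in
databases next to their mechanistic ancestors:

* **HMOD**, a block-structured ASCII format (normative grammar in
  [HMOD-SPEC.md](HMOD-SPEC.md)) holding the mechanistic blocks plus an
  optional `[ML]` block with the network's weights and wiring;
* converters SBML → HMOD and HMOD → SBML with full validators on both
  sides (every problem is a coded report entry, never a crash);
* a **compiler** that turns the network into plain SBML: one constant
  parameter per weight/bias, one assignment rule per scaled input,
  hidden node and output node (tanh is native content MathML), with the
  targeted reaction's kinetic law replaced by the output symbol — and a
  decompiler that recovers the weights bit-exactly;
* a deterministic stiff-capable ODE simulator used to verify that every
  conversion and compilation preserves trajectories.

Training is out of scope: weights arrive trained (portable `.annw` text
container; a minimal Keras-H5 reader is available when `h5py` is
installed).

## Worked example

```python
import hybkit as hk
from hybkit.fixtures import make_toy_model, make_rate_mimicking_ann

# mechanistic model: S -> P (Michaelis-Menten), P -> 0 (mass action)
m = make_toy_model("michaelis-menten-pathway", seed=1)

# fit a 1-hidden-layer tanh network (20 nodes) to the uptake rate law
ann = make_rate_mimicking_ann(m, "uptake", n_hidden=20, seed=1)
print(f"fit error: {ann.metadata['fit_error']:.3e}")

# compile it into the model and compare simulations
hybrid, plan = hk.hybridize(m, ann)
mech = hk.run(m, t_end=10.0, n_points=100)
hyb = hk.run(hybrid, t_end=10.0, n_points=100)
cmp = hk.compare_trajectories(mech, hyb)
print({k: f"{v:.2e}" for k, v in cmp.max_abs.items()})

# the hybrid model is plain SBML
xml = hk.write_sbml(hybrid)
print(hk.validate_sbml_structure(xml).is_empty())
```

prints

```
fit error: 6.272e-08
{'S': '1.69e-08', 'P': '1.67e-08', 'total': '3.98e-09'}
True
```

— the fitted network reproduces the Michaelis–Menten rate to 6·10⁻⁸
over the sampled state box, the compiled hybrid model's trajectory stays
within ~2·10⁻⁸ of the mechanistic one on every column, and the emitted
hybrid SBML validates cleanly.

The same workflow from a shell:

```
hybkit convert model.xml --out model.hmod      # SBML -> HMOD
hybkit hybridize model.hmod net.annw --out hybrid.xml
hybkit validate hybrid.xml
hybkit simulate hybrid.xml --t-end 10 --out traj.csv
hybkit fixtures --out-dir fixtures --seed 1    # regenerate the demo inputs
```

Exit codes: 0 success (warnings allowed), 1 validation errors, 2 fatal.

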