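# unionpid

Partial information decomposition (PID) for discrete systems, built around a
**conditional-independence union-information measure** and the synergy it
induces, together with the degradation-order (Blackwell) measures and the
classic synergy measures used for comparison.

## The problem

Given a joint pmf p(y1, …, yn, t) over *source* variables Y = (Y1, …, Yn) and
a *target* T, PID asks how the mutual information I(Y;T) decomposes into
redundant (R), unique (U_i) and synergistic (S) parts — for two sources,

    I(T;Y) = R + U1 + U2 + S.

Rather than starting from a redundancy measure, this package starts from
**union information** — the information about T available from at least one
source in a collection — and defines synergy as what is left:

    S(α → T) = I(Y;T) − I_∪(α → T).

The core measure treats each source A_i as an agent that knows p(t) and its
own conditional p(A_i | t).  Agents that pool conditionals but cannot observe
jointly can only build compositions

    q(t, a) = p(t) · ∏_blocks p(block | t)

over partitions of A = ⋃A_i whose blocks fit inside single sources.  The
union information is the best such composition, clipped by what the true
joint actually provides:

    I_∪^CI(A1, …, Am → T) = min{ I(A;T), max_{q ∈ Q} I_q(A;T) },
    S^CI = I(Y;T) − I_∪^CI  =  max{0, I(Y;T) − I_q(Y;T)}   (two sources).

Synergy, under this reading, is the information that is invisible to any
model that assumes the sources conditionally independent given the target —
a notion directly useful wherever conditional-independence ("naive-Bayes
like") models are used as surrogates for joint observation, e.g. in gene
regulatory network inference or neural population coding.

Also implemented, behind the same pmf containers:

* **Degradation-order redundancy** I_∩^d: the most informative channel
  Blackwell-dominated by every source channel K(i) = p(A_i|t), maximized
  exactly by vertex enumeration of the garbling polytope.
* **Fixed-marginal union information** I_∪^d (≡ I_∪^VK / BROJA-style): the
  convex minimization of I(⋃A_i;T) over joints preserving each p(A_i, T),
  and its synergy S^d.
* **Legacy synergies**: Williams–Beer S^WB (inclusion–exclusion over the
  expected minimum specific information), whole-minus-sum S^WMS,
  correlational importance S^ΔI, and the dependency-decomposition synergy
  S^dep with its maximum-entropy (iterative proportional fitting)
  distributions.
* A **distribution zoo** (XOR, AND, COPY, BOOM, RDNXOR, RDNUNQXOR,
  XORLOSES, XORMULTICOAL, the adapted ReducedOR/XOR families, …) and an
  **axiom harness** that checks the Williams–Beer axioms extended to union
  information, the derived synergy properties, and the counterexamples that
  reject target monotonicity, the target data-processing inequality and
  channel convexity.

## Worked example

The AND gate (Y1, Y2 iid fair bits, T = Y1 AND Y2):

```sh
unionpid zoo --name AND --out and.tsv
unionpid compute --pmf and.tsv --target T --measure ci
```

prints

```json
{
  "results": [
    {
      "measure": "union_ci",
      "value": 0.5408520829727554,
      "clipped": false,
      "argmax_partition": [["Y1"], ["Y2"]],
      "synergy_ci": 0.2704260414863775,
      "atoms": {
        "R": 0.08170416594551044,
        "U1": 0.2295739585136225,
        "U2": 0.2295739585136225,
        "S": 0.2704260414863775
      },
      "mutual_information": 0.8112781244591329
    }
  ]
}
```

Reading: the two bits share I(Y;T) ≈ 0.811 bits about the AND output; a
conditional-independence composition of their individual channels captures
I_∪^CI ≈ 0.541 bits, so S^CI ≈ 0.270 bits (about a third of the total) exist
only in the joint observation.  The remaining atoms follow from the bivariate
system: U1 = U2 ≈ 0.230 and R ≈ 0.082 bits.

The same library calls are available programmatically:

```python
from unionpid import make_distribution, synergy_ci, SourceCollection

pmf = make_distribution("AND")
synergy_ci(pmf)                                   # 0.2704260414863775
synergy_ci(pmf, SourceCollection.of("Y1"))        # I(Y2;T|Y1) = 0.5
```

Other subcommands: `unionpid compute --measure d|rd|wb|wms|deltai|dep`,
`unionpid zoo --name ADAPTED_XOR --param r=0.25`, and
`unionpid axioms --trials 200 --seed 1 --report report.json`.

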