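# Greek letters spelled out during chemical-name normalization.
# Editable: naming differences between ontologies are open-ended, so new
# mappings can be added without touching code.
alpha: "α"
beta: "β"
gamma: "γ"
delta: "δ"
epsilon: "ε"
zeta: "ζ"
eta: "η"
theta: "θ"
iota: "ι"
kappa: "κ"
lambda: "λ"
mu: "μ"
nu: "ν"
xi: "ξ"
omicron: "ο"
pi: "π"
rho: "ρ"
sigma: "σ"
tau: "τ"
upsilon: "υ"
phi: "φ"
chi: "χ"
psi: "ψ"
omega: "ω"
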