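activate	activate|activates|activated|activating|activation|activations|activator|activators
associate	associate|associates|associated|associating|association
bind	bind|binds|binding|bound
block	block|blocks|blocked|blocking|blocker|blockers
cause	cause|causes|caused|causing
depend	depend|depends|depended|depending|dependence|dependent
express	express|expresses|expressed|expressing|expression|expressions
induce	induce|induces|induced|inducing|induction
inhibit	inhibit|inhibits|inhibited|inhibiting|inhibition|inhibitor|inhibitors
interact	interact|interacts|interacted|interacting|interaction|interactions|interactor|interactors
phosphorylate	phosphorylate|phosphorylates|phosphorylated|phosphorylating|phosphorylation
regulate	regulate|regulates|regulated|regulating|regulation|regulator|regulators
suppress	suppress|suppresses|suppressed|suppressing|suppression|suppressor|suppressors
transform	transform|transforms|transformed|transforming|transformation
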