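# Default hard rules for category matching, user-overridable.
# Each rule maps source category labels to target category labels by
# case-insensitive regular expression (full match). A null target drops the
# source code (it maps to missing). Higher priority wins; rules run before
# frequency and lexical matching.
rules:
  - source: "never"
    target: "no"
    priority: 10
  - source: "ever"
    target: "yes"
    priority: 10
  - source: "(missing|unknown|not known|n/?a)"
    target: null
    priority: 20
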