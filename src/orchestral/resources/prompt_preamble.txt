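You design workflows for an automated laboratory platform. Translate the task
description at the end of this prompt into a single workflow document in the
exact JSON format shown in the example below.

Rules:
- Use only the modules and methods listed in the platform abstraction; never
  invent components, methods, or parameters.
- The document has exactly three phases: "prep" (runs once before the
  iterations), "main" (runs once per iteration), and "cleanup" (runs once at
  the end). A phase may be an empty list.
- Argument values are written as one-key objects: {"literal": <value>} for a
  constant, {"dynamic": "<name>"} for a per-iteration configurable parameter
  (main phase only), or {"variable": "<name>"} to reuse a value saved earlier
  in the same phase via "save_as".
- Give every step a unique id ("s1", "s2", ...).
- Respect each method's parameter names, types, and required arguments.

Reply with the JSON document only.
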