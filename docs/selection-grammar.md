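# Selection-expression grammar

Selections are built from strings in a small VMD-like language.  The full
grammar in EBNF:

```
expr     = or_expr ;
or_expr  = and_expr , { "or" , and_expr } ;
and_expr = unary , { "and" , unary } ;
unary    = "not" , unary | primary ;
primary  = "(" , expr , ")"
         | "all"
         | "name"    , word , { word }
         | "resname" , word , { word }
         | "chain"   , word , { word }
         | "resid"   , range , { range }
         | "index"   , range , { range }
         | "within"  , number , "of" , "(" , expr , ")" ;
range    = integer , [ ( "-" | "to" ) , integer ] ;
word     = letter , { letter | digit | "'" | "*" | "+" | "_" } ;
```

Semantics:

- `index` is 0-based and ranges are **inclusive**: `index 2-5` = atoms
  2, 3, 4, 5.  `resid` matches the residue ids read from the file,
  verbatim (PDB resids are 1-based by convention, but any integers the
  file contains are accepted).
- `name`, `resname`, `chain` take one or more whitespace-separated values
  and match any of them (an implicit `or`).
- `within r of (E)` selects every atom of the **whole system** whose
  minimum-image distance (when the frame has a periodic box) to any atom
  matched by `E` is `<= r` nanometers.  Ties at exactly `r` are included.
  The atoms of `E` themselves are part of the result by default; pass
  `within_self=False` to `select()` to exclude them.
- `and` binds tighter than `or`; `not` binds tightest; parentheses
  override.
- An expression that matches nothing is an **error**
  (`EmptySelectionError`), not an empty view; use `System.try_select` to
  probe without raising.

Examples:

```
name CA
name CA C N O and chain A
resid 10-25 100
within 1.0 of (resname LIG)
not (chain B or resid 1)
```

Inside `Selection.subselect`, the same grammar applies but candidates are
restricted to the parent's atoms; the inner expression of `within` is still
evaluated system-wide, so `subselect(e)` always equals the system-wide
selection of `e` intersected with the parent.
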