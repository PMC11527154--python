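"""Tokenizer and recursive-descent parser for model text.

The grammar is a reconstruction from typical usage: ``;``-terminated
statements, ``//`` comments, ``+`` as multiset separator, ``{}`` for
compartment contents and ``()`` for attribute lists -- with the two
interchangeable on a species occurrence, as in ``C(?c1+?c2)``.  A
bare name inside ``(...)`` is ambiguous between an attribute binding
and a content species; it is recorded as such and resolved during
type checking, when species names are known.

Counts in init/product multisets are unary or parenthesized
expressions (``10 A``, ``(2+3) A``, ``(L.n) mRNA``); a bare ``+``
inside a count must be parenthesized because ``+`` separates multiset
elements.
"""

from __future__ import annotations

import re
from typing import List, Optional, Tuple, Union

from . import syntax as S
from .units import Unit, is_unit_name, lookup_unit

__all__ = ["parse", "ParseError", "tokenize"]


class ParseError(SyntaxError):
    """Syntax error with line/column and the offending token."""

    def __init__(self, msg: str, line: int, col: int, token: str = ""):
        super().__init__(f"{line}:{col}: {msg}" + (f" (at {token!r})" if token else ""))
        self.line = line
        self.col = col
        self.token = token


KEYWORDS = {"const", "func", "species", "init", "observe",
            "if", "then", "else", "in", "enum"}

_TOKEN_RE = re.compile(r"""
    (?P<WS>\s+)
  | (?P<COMMENT>//[^\n]*)
  | (?P<NUMBER>(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?)
  | (?P<SEQVAR>\?[A-Za-z_][A-Za-z0-9_]*)
  | (?P<NAME>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<STRING>"[^"\n]*")
  | (?P<OP>->|==|!=|<=|>=|&&|\|\||[-+*/^@;,.:#(){}\[\]<>=])
""", re.VERBOSE)


class Token:
    __slots__ = ("kind", "text", "line", "col")

    def __init__(self, kind: str, text: str, line: int, col: int):
        self.kind = kind
        self.text = text
        self.line = line
        self.col = col

    def __repr__(self) -> str:  # pragma: no cover
        return f"Token({self.kind},{self.text!r}@{self.line}:{self.col})"


def tokenize(text: str) -> List[Token]:
    # normalize typographic quotes
    text = text.replace("“", '"').replace("”", '"')
    toks: List[Token] = []
    line, linestart = 1, 0
    pos = 0
    n = len(text)
    while pos < n:
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise ParseError("unexpected character", line, pos - linestart + 1,
                             text[pos])
        kind = m.lastgroup
        tok_text = m.group()
        col = m.start() - linestart + 1
        if kind in ("WS", "COMMENT"):
            nl = tok_text.count("\n")
            if nl:
                line += nl
                linestart = m.start() + tok_text.rfind("\n") + 1
        else:
            toks.append(Token(kind, tok_text, line, col))
        pos = m.end()
    toks.append(Token("EOF", "", line, n - linestart + 1))
    return toks


class _Parser:
    def __init__(self, tokens: List[Token]):
        self.toks = tokens
        self.i = 0

    # -- token helpers ---------------------------------------------------
    @property
    def cur(self) -> Token:
        return self.toks[self.i]

    def peek(self, ahead: int = 1) -> Token:
        j = min(self.i + ahead, len(self.toks) - 1)
        return self.toks[j]

    def loc(self) -> S.Loc:
        return S.Loc(self.cur.line, self.cur.col)

    def error(self, msg: str) -> ParseError:
        t = self.cur
        return ParseError(msg, t.line, t.col, t.text)

    def advance(self) -> Token:
        t = self.cur
        if t.kind != "EOF":
            self.i += 1
        return t

    def accept(self, text: str) -> Optional[Token]:
        if self.cur.text == text and self.cur.kind in ("OP", "NAME"):
            return self.advance()
        return None

    def expect(self, text: str) -> Token:
        t = self.accept(text)
        if t is None:
            raise self.error(f"expected {text!r}")
        return t

    def expect_name(self) -> Token:
        if self.cur.kind != "NAME":
            raise self.error("expected identifier")
        if self.cur.text in KEYWORDS:
            raise self.error(f"keyword {self.cur.text!r} not allowed here")
        return self.advance()

    # -- units -----------------------------------------------------------
    def _try_unit_suffix(self) -> Tuple[Optional[Unit], Optional[str]]:
        """Parse a unit suffix after a numeric literal, if present.

        Recognized: ``um``, ``um^3``, ``mol / L``, ``1 / s`` (the
        leading 1 handled by the caller via a bare ``/ unit``).  Only
        consumes tokens while they denote known unit names.
        """
        unit: Optional[Unit] = None
        parts: List[str] = []

        def at_unit() -> bool:
            return self.cur.kind == "NAME" and is_unit_name(self.cur.text)

        if at_unit():
            unit = self._unit_factor(parts)
        elif self.cur.text == "/" and self.peek().kind == "NAME" \
                and is_unit_name(self.peek().text):
            unit = Unit()
        else:
            return None, None
        while self.cur.text in ("/", "*"):
            op = self.cur.text
            if not (self.peek().kind == "NAME" and is_unit_name(self.peek().text)):
                break
            self.advance()
            parts.append(op)
            factor = self._unit_factor(parts)
            unit = unit / factor if op == "/" else unit * factor
        return unit, " ".join(parts) if parts else None

    def _unit_factor(self, parts: List[str]) -> Unit:
        name = self.advance().text
        u = lookup_unit(name)
        txt = name
        if self.cur.text == "^" and self.peek().kind == "NUMBER":
            self.advance()
            exp_tok = self.advance()
            exp = int(float(exp_tok.text))
            u = u ** exp
            txt += f"^{exp}"
        parts.append(txt)
        return u

    # -- expressions -----------------------------------------------------
    def parse_expr(self) -> S.Expr:
        return self._or()

    def _or(self) -> S.Expr:
        e = self._and()
        while self.cur.text == "||":
            loc = self.loc()
            self.advance()
            e = S.BinOp("||", e, self._and(), loc=loc)
        return e

    def _and(self) -> S.Expr:
        e = self._cmp()
        while self.cur.text == "&&":
            loc = self.loc()
            self.advance()
            e = S.BinOp("&&", e, self._cmp(), loc=loc)
        return e

    def _cmp(self) -> S.Expr:
        e = self._add()
        if self.cur.text in ("==", "!=", "<", ">", "<=", ">="):
            op = self.advance().text
            e = S.BinOp(op, e, self._add())
        return e

    def _add(self) -> S.Expr:
        e = self._mul()
        while self.cur.text in ("+", "-"):
            op = self.advance().text
            e = S.BinOp(op, e, self._mul())
        return e

    def _mul(self) -> S.Expr:
        e = self._unary()
        while self.cur.text in ("*", "/"):
            op = self.advance().text
            e = S.BinOp(op, e, self._unary())
        return e

    def _unary(self) -> S.Expr:
        if self.cur.text == "-":
            loc = self.loc()
            self.advance()
            return S.UnOp("-", self._unary(), loc=loc)
        return self._power()

    def _power(self) -> S.Expr:
        e = self._primary()
        if self.cur.text == "^":
            self.advance()
            return S.BinOp("^", e, self._unary())  # right associative
        return e

    def _primary(self) -> S.Expr:
        t = self.cur
        loc = self.loc()
        if t.kind == "NUMBER":
            self.advance()
            value = float(t.text)
            unit, unit_text = self._try_unit_suffix()
            return S.Num(value, unit=unit, unit_text=unit_text, loc=loc)
        if t.kind == "STRING":
            self.advance()
            return S.Str(t.text[1:-1], loc=loc)
        if t.text == "#":
            self.advance()
            name = self.expect_name()
            return S.CountRef(name.text, loc=loc)
        if t.text == "(":
            self.advance()
            e = self.parse_expr()
            self.expect(")")
            return e
        if t.text == "if":
            self.advance()
            cond = self.parse_expr()
            self.expect("then")
            then = self.parse_expr()
            self.expect("else")
            els = self.parse_expr()
            return S.IfExpr(cond, then, els, loc=loc)
        if t.kind == "NAME":
            name = self.expect_name()
            if self.cur.text == "." and self.peek().kind == "NAME":
                self.advance()
                attr = self.expect_name()
                return S.AttrRef(name.text, attr.text, loc=loc)
            if self.cur.text == "(":
                self.advance()
                args: List[S.Expr] = []
                if self.cur.text != ")":
                    args.append(self.parse_expr())
                    while self.accept(","):
                        args.append(self.parse_expr())
                self.expect(")")
                return S.Call(name.text, tuple(args), loc=loc)
            return S.Name(name.text, loc=loc)
        raise self.error("expected expression")

    # -- patterns --------------------------------------------------------
    _CONSTRAINT_OPS = ("==", "!=", "<=", ">=", "<", ">", "=")

    def parse_pattern(self, stop: Tuple[str, ...]) -> S.Pattern:
        """Multiset pattern: elements separated by '+', possibly empty."""
        elems: List[S.PatternElem] = []
        if self.cur.text in stop or self.cur.kind == "EOF":
            return tuple(elems)
        elems.append(self.parse_elem())
        while self.accept("+"):
            elems.append(self.parse_elem())
        return tuple(elems)

    def parse_elem(self) -> S.PatternElem:
        loc = self.loc()
        if self.cur.kind == "SEQVAR":
            name = self.advance().text[1:]
            weight = None
            if self.accept("["):
                weight = self.parse_expr()
                self.expect("]")
            return S.SeqVar(name, weight, loc=loc)
        count: Optional[S.Expr] = None
        if self.cur.kind == "NUMBER":
            # plain numeric multiplicity; no unit suffix in pattern position
            count = S.Num(float(self.advance().text), loc=loc)
        elif self.cur.text == "(":
            self.advance()
            count = self.parse_expr()
            self.expect(")")
        elif self.cur.kind == "NAME" and self.peek().kind == "NAME" \
                and self.cur.text not in KEYWORDS \
                and self.peek().text not in KEYWORDS:
            # `n A` -- constant multiplicity reference
            count = S.Name(self.advance().text, loc=loc)
        return self._species_term(count, loc)

    def _species_term(self, count: Optional[S.Expr], loc: S.Loc) -> S.PatternNode:
        species = self.expect_name().text
        attrs: List[S.AttrConstraint] = []
        ambiguous: List[str] = []
        content: Optional[List[S.PatternElem]] = None
        bind: Optional[str] = None

        if self.accept("("):
            content_from_parens = self._paren_items(attrs, ambiguous)
            if content_from_parens is not None:
                content = content_from_parens
        if self.cur.text == ":" and self.peek().kind == "NAME":
            self.advance()
            bind = self.expect_name().text
        if self.accept("{"):
            if content is None:
                content = []
            content.extend(self.parse_pattern(stop=("}",)))
            self.expect("}")
        return S.PatternNode(species, tuple(attrs), bind,
                             tuple(content) if content is not None else None,
                             count, tuple(ambiguous), loc=loc)

    def _paren_items(self, attrs: List[S.AttrConstraint],
                     ambiguous: List[str]) -> Optional[List[S.PatternElem]]:
        """Parse comma-separated items of a ``(...)`` list.

        Returns collected content elements (possibly empty list) if any
        group was content-like, else None.
        """
        content: List[S.PatternElem] = []
        saw_content = False
        if self.accept(")"):
            return None
        while True:
            loc = self.loc()
            if self.cur.kind == "NAME" and self.peek().text in self._CONSTRAINT_OPS \
                    and self.cur.text not in KEYWORDS:
                name = self.advance().text
                op = self.advance().text
                expr = self.parse_expr()
                attrs.append(S.AttrConstraint(name, op, expr, loc=loc))
            elif self.cur.kind == "NAME" and self.peek().text in (",", ")") \
                    and self.cur.text not in KEYWORDS:
                # bare name: attribute binding or content species -- defer
                ambiguous.append(self.advance().text)
            else:
                saw_content = True
                content.append(self.parse_elem())
                while self.accept("+"):
                    content.append(self.parse_elem())
            if self.accept(","):
                continue
            self.expect(")")
            break
        return content if (saw_content or content) else None

    # -- statements ------------------------------------------------------
    def parse_model(self) -> S.ModelAST:
        species: List[S.SpeciesDecl] = []
        constants: List[S.ConstDecl] = []
        functions: List[S.FuncDecl] = []
        rules: List[S.RuleDef] = []
        observables: List[S.ObserveDecl] = []
        init: Optional[S.InitDecl] = None
        while self.cur.kind != "EOF":
            t = self.cur
            if t.text == "const":
                constants.append(self._const_decl())
            elif t.text == "func":
                functions.append(self._func_decl())
            elif t.text == "species":
                species.append(self._species_decl())
            elif t.text == "init":
                if init is not None:
                    raise self.error("duplicate init section")
                init = self._init_decl()
            elif t.text == "observe":
                observables.append(self._observe_decl())
            else:
                rules.append(self._rule())
        return S.ModelAST(tuple(species), tuple(constants), tuple(functions),
                          init, tuple(rules), tuple(observables))

    def _const_decl(self) -> S.ConstDecl:
        loc = self.loc()
        self.expect("const")
        name = self.expect_name().text
        if not (self.accept(":") or self.accept("=")):
            raise self.error("expected ':' or '=' in constant definition")
        expr = self.parse_expr()
        self.expect(";")
        return S.ConstDecl(name, expr, loc=loc)

    def _func_decl(self) -> S.FuncDecl:
        loc = self.loc()
        self.expect("func")
        name = self.expect_name().text
        self.expect("(")
        params: List[str] = []
        if self.cur.text != ")":
            params.append(self.expect_name().text)
            while self.accept(","):
                params.append(self.expect_name().text)
        self.expect(")")
        if not (self.accept(":") or self.accept("=")):
            raise self.error("expected ':' or '=' in function definition")
        body = self.parse_expr()
        self.expect(";")
        return S.FuncDecl(name, tuple(params), body, loc=loc)

    def _species_decl(self) -> S.SpeciesDecl:
        loc = self.loc()
        self.expect("species")
        name = self.expect_name().text
        attrs: List[S.AttributeDecl] = []
        self.expect("(")
        if self.cur.text != ")":
            attrs.append(self._attr_decl())
            while self.accept(","):
                attrs.append(self._attr_decl())
        self.expect(")")
        self.expect(";")
        return S.SpeciesDecl(name, tuple(attrs), loc=loc)

    def _attr_decl(self) -> S.AttributeDecl:
        loc = self.loc()
        name = self.expect_name().text
        self.expect(":")
        kind_tok = self.advance()
        kind = kind_tok.text
        enum_values: Tuple[str, ...] = ()
        if kind == "enum":
            self.expect("{")
            vals: List[str] = []
            while self.cur.text != "}":
                if self.cur.kind == "STRING":
                    vals.append(self.advance().text[1:-1])
                else:
                    vals.append(self.expect_name().text)
                self.accept(",")
            self.expect("}")
            enum_values = tuple(vals)
        elif kind not in ("int", "real", "string", "nf_int", "nf_real"):
            raise ParseError(f"unknown attribute type {kind!r}",
                             kind_tok.line, kind_tok.col, kind)
        unit, unit_text = self._try_unit_suffix()
        return S.AttributeDecl(name, kind, unit, unit_text, enum_values, loc=loc)

    def _init_decl(self) -> S.InitDecl:
        loc = self.loc()
        self.expect("init")
        content = self.parse_pattern(stop=(";",))
        self.expect(";")
        return S.InitDecl(content, loc=loc)

    def _observe_decl(self) -> S.ObserveDecl:
        loc = self.loc()
        self.expect("observe")
        name = self.expect_name().text
        self.expect(":")
        elem = self.parse_elem()
        if not isinstance(elem, S.PatternNode):
            raise self.error("observable pattern must be a species pattern")
        scope = None
        if self.accept("in"):
            scope = self.expect_name().text
        self.expect(";")
        return S.ObserveDecl(name, elem, scope, loc=loc)

    def _rule(self) -> S.RuleDef:
        loc = self.loc()
        lhs = self.parse_pattern(stop=("->",))
        self.expect("->")
        rhs = self.parse_pattern(stop=("@",))
        self.expect("@")
        rate = self.parse_expr()
        self.expect(";")
        return S.RuleDef(lhs, rhs, rate, loc=loc)


def parse(text: str) -> S.ModelAST:
    """Parse model text into an AST, preserving source locations."""
    return _Parser(tokenize(text)).parse_model()
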