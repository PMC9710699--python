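"""Hand-written lexer and recursive-descent parser for VQL.

Keywords are case-insensitive, identifiers are lowercased, and string
literals accept straight (``'``) and typographic (``‘`` ``’``)
quote characters interchangeably.  Operator precedence is
NOT > AND > OR, with parentheses overriding.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ast import (
    Comparison,
    CreateSelection,
    CreateSetOp,
    Drop,
    FieldRef,
    ImportWordset,
    Logical,
    Not,
    SelectStmt,
)

__all__ = ["parse_vql", "VqlSyntaxError", "KEYWORDS"]

KEYWORDS = frozenset(
    """select from where order by limit offset create drop import as
       wordset selection and or not in is null asc desc intersect
       samples""".split()
)

_QUOTES = {"'", "‘", "’"}
_OPERATORS = ("!=", "<=", ">=", "=", "<", ">", "~", "(", ")", ",", ".",
              "[", "]", "&", "|", "-")


class VqlSyntaxError(ValueError):
    """Syntax error with 1-based line/column and the offending token."""

    def __init__(self, message: str, line: int, col: int, token: str = ""):
        self.line, self.col, self.token = line, col, token
        where = f"line {line}, column {col}"
        if token:
            where += f" near {token!r}"
        super().__init__(f"VQL syntax error at {where}: {message}")


@dataclass(frozen=True)
class _Token:
    kind: str  # IDENT | STRING | INT | FLOAT | OP | EOF
    value: object
    line: int
    col: int

    @property
    def text(self) -> str:
        return str(self.value)


def _tokenize(text: str):
    tokens = []
    i, line, col = 0, 1, 1
    n = len(text)

    def err(msg, tok=""):
        raise VqlSyntaxError(msg, line, col, tok)

    while i < n:
        ch = text[i]
        if ch == "\n":
            i, line, col = i + 1, line + 1, 1
            continue
        if ch.isspace():
            i, col = i + 1, col + 1
            continue
        start_line, start_col = line, col
        if ch in _QUOTES:
            i, col = i + 1, col + 1
            buf = []
            closed = False
            while i < n:
                ch = text[i]
                if ch == "\n":
                    break
                if ch in _QUOTES:
                    if ch == "'" and i + 1 < n and text[i + 1] == "'":
                        buf.append("'")
                        i, col = i + 2, col + 2
                        continue
                    i, col = i + 1, col + 1
                    closed = True
                    break
                buf.append(ch)
                i, col = i + 1, col + 1
            if not closed:
                raise VqlSyntaxError(
                    "unterminated string literal", start_line, start_col
                )
            tokens.append(_Token("STRING", "".join(buf), start_line, start_col))
            continue
        if ch.isdigit():
            j = i
            while j < n and text[j].isdigit():
                j += 1
            is_float = False
            if j < n and text[j] == "." and j + 1 < n and text[j + 1].isdigit():
                is_float = True
                j += 1
                while j < n and text[j].isdigit():
                    j += 1
            if j < n and text[j] in "eE":
                k = j + 1
                if k < n and text[k] in "+-":
                    k += 1
                if k < n and text[k].isdigit():
                    is_float = True
                    j = k
                    while j < n and text[j].isdigit():
                        j += 1
            lexeme = text[i:j]
            tokens.append(
                _Token("FLOAT" if is_float else "INT",
                       float(lexeme) if is_float else int(lexeme),
                       start_line, start_col)
            )
            col += j - i
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] == "_"):
                j += 1
            tokens.append(_Token("IDENT", text[i:j].lower(), start_line, start_col))
            col += j - i
            i = j
            continue
        matched = None
        for op in _OPERATORS:
            if text.startswith(op, i):
                matched = op
                break
        if matched is None:
            err(f"unexpected character {ch!r}", ch)
        tokens.append(_Token("OP", matched, start_line, start_col))
        i += len(matched)
        col += len(matched)
    tokens.append(_Token("EOF", "", line, col))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.pos = 0

    # -- primitives --------------------------------------------------------

    @property
    def cur(self) -> _Token:
        return self.tokens[self.pos]

    def advance(self) -> _Token:
        tok = self.cur
        if tok.kind != "EOF":
            self.pos += 1
        return tok

    def error(self, message: str, tok: _Token | None = None):
        tok = tok or self.cur
        raise VqlSyntaxError(message, tok.line, tok.col, tok.text)

    def at_kw(self, *words: str) -> bool:
        return self.cur.kind == "IDENT" and self.cur.value in words

    def take_kw(self, *words: str) -> bool:
        if self.at_kw(*words):
            self.advance()
            return True
        return False

    def expect_kw(self, word: str):
        if not self.take_kw(word):
            self.error(f"expected {word.upper()}")

    def at_op(self, *ops: str) -> bool:
        return self.cur.kind == "OP" and self.cur.value in ops

    def take_op(self, *ops: str) -> bool:
        if self.at_op(*ops):
            self.advance()
            return True
        return False

    def expect_op(self, op: str):
        if not self.take_op(op):
            self.error(f"expected {op!r}")

    def ident(self, what: str = "identifier") -> str:
        if self.cur.kind != "IDENT":
            self.error(f"expected {what}")
        if self.cur.value in KEYWORDS:
            self.error(f"expected {what}, found keyword")
        return self.advance().value

    # -- grammar -----------------------------------------------------------

    def statement(self):
        if self.take_kw("select"):
            stmt = self.select_rest()
        elif self.take_kw("create"):
            stmt = self.create_rest()
        elif self.take_kw("drop"):
            stmt = self.drop_rest()
        elif self.take_kw("import"):
            stmt = self.import_rest()
        else:
            self.error("expected SELECT, CREATE, DROP or IMPORT")
        if self.cur.kind != "EOF":
            self.error("unexpected trailing input")
        return stmt

    def select_rest(self) -> SelectStmt:
        fields = [self.field_ref("field name")]
        while self.take_op(","):
            fields.append(self.field_ref("field name"))
        self.expect_kw("from")
        source = self.ident("selection name")
        filt = self.or_expr() if self.take_kw("where") else None
        order_by: list = []
        if self.take_kw("order"):
            self.expect_kw("by")
            order_by.append(self.order_key())
            while self.take_op(","):
                order_by.append(self.order_key())
        limit = offset = None
        if self.take_kw("limit"):
            limit = self.int_literal("LIMIT count")
            if self.take_kw("offset"):
                offset = self.int_literal("OFFSET count")
        return SelectStmt(tuple(fields), source, filt, tuple(order_by),
                          limit, offset)

    def create_rest(self):
        name = self.ident("selection name")
        if self.take_op("="):
            left = self.ident("selection name")
            if not self.at_op("&", "|", "-"):
                self.error("expected set operator '&', '|' or '-'")
            op = self.advance().value
            right = self.ident("selection name")
            return CreateSetOp(name, left, op, right)
        self.expect_kw("from")
        source = self.ident("selection name")
        filt = self.or_expr() if self.take_kw("where") else None
        bed = None
        if self.take_kw("intersect"):
            if self.cur.kind != "STRING":
                self.error("expected quoted BED file path after INTERSECT")
            bed = self.advance().value
        return CreateSelection(name, source, filt, bed)

    def drop_rest(self) -> Drop:
        if self.take_kw("selection"):
            target = "selection"
        elif self.take_kw("wordset"):
            target = "wordset"
        else:
            self.error("expected SELECTION or WORDSET after DROP")
        return Drop(target, self.ident(f"{target} name"))

    def import_rest(self) -> ImportWordset:
        self.expect_kw("wordset")
        if self.cur.kind != "STRING":
            self.error("expected quoted file path after IMPORT WORDSET")
        path = self.advance().value
        self.expect_kw("as")
        return ImportWordset(path, self.ident("wordset name"))

    def order_key(self):
        ref = self.field_ref("ORDER BY field")
        direction = "ASC"
        if self.take_kw("desc"):
            direction = "DESC"
        else:
            self.take_kw("asc")
        return (ref, direction)

    def int_literal(self, what: str) -> int:
        if self.cur.kind != "INT":
            self.error(f"expected integer {what}")
        return self.advance().value

    def field_ref(self, what: str = "field") -> FieldRef:
        if self.at_kw("samples"):
            self.advance()
            self.expect_op("[")
            if self.cur.kind != "STRING":
                self.error("expected quoted sample name")
            sample = self.advance().value
            self.expect_op("]")
            self.expect_op(".")
            name = self.ident("sample field name")
            return FieldRef(name, "sample", sample)
        name = self.ident(what)
        if self.take_op("."):
            if name != "ann":
                self.error(
                    f"unknown field namespace {name!r} (expected 'ann' or "
                    "samples['X'])"
                )
            return FieldRef(self.ident("annotation field name"), "ann")
        return FieldRef(name)

    # expressions: OR < AND < NOT < comparison

    def or_expr(self):
        children = [self.and_expr()]
        while self.take_kw("or"):
            children.append(self.and_expr())
        return children[0] if len(children) == 1 else Logical("OR", tuple(children))

    def and_expr(self):
        children = [self.not_expr()]
        while self.take_kw("and"):
            children.append(self.not_expr())
        return children[0] if len(children) == 1 else Logical("AND", tuple(children))

    def not_expr(self):
        if self.take_kw("not"):
            return Not(self.not_expr())
        return self.primary()

    def primary(self):
        if self.take_op("("):
            node = self.or_expr()
            self.expect_op(")")
            return node
        return self.comparison()

    def comparison(self) -> Comparison:
        ref = self.field_ref("field in condition")
        if self.at_op("=", "!=", "<", "<=", ">", ">="):
            op = self.advance().value
            return Comparison(ref, op, self.literal())
        if self.take_op("~"):
            if self.cur.kind != "STRING":
                self.error("expected quoted regex pattern after '~'")
            return Comparison(ref, "~", self.advance().value)
        if self.take_kw("is"):
            negated = self.take_kw("not")
            self.expect_kw("null")
            return Comparison(ref, "IS NOT NULL" if negated else "IS NULL")
        if self.take_kw("not"):
            self.expect_kw("in")
            return Comparison(ref, "NOT IN", self.literal_list())
        if self.take_kw("in"):
            if self.take_kw("wordset"):
                if self.cur.kind == "STRING":
                    return Comparison(ref, "IN WORDSET", self.advance().value)
                return Comparison(ref, "IN WORDSET", self.ident("wordset name"))
            return Comparison(ref, "IN", self.literal_list())
        self.error("expected a comparison operator")

    def literal(self):
        negative = self.take_op("-")
        tok = self.cur
        if tok.kind in ("INT", "FLOAT"):
            self.advance()
            return -tok.value if negative else tok.value
        if negative:
            self.error("expected a number after '-'")
        if tok.kind == "STRING":
            self.advance()
            return tok.value
        self.error("expected a literal value")

    def literal_list(self) -> tuple:
        self.expect_op("(")
        items = [self.literal()]
        while self.take_op(","):
            items.append(self.literal())
        self.expect_op(")")
        return tuple(items)


def parse_vql(text: str):
    """Parse one VQL statement into its AST.

    Raises :class:`VqlSyntaxError` with line/column diagnostics.
    """
    if not text or not text.strip():
        raise VqlSyntaxError("empty statement", 1, 1)
    return _Parser(text).statement()
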