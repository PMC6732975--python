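# Default English stopword list: articles, pronouns, prepositions,
# conjunctions and auxiliary verbs (all inflections, so that lemmatization
# never re-creates a stopword). Content words are never listed here.
a
an
the
and
or
but
nor
so
yet
if
then
else
when
while
because
as
than
that
this
these
those
i
me
my
mine
we
us
our
ours
you
your
yours
he
him
his
she
her
hers
it
its
they
them
their
theirs
who
whom
whose
which
what
where
why
how
is
am
are
was
were
be
been
being
do
does
did
doing
done
have
has
had
having
will
would
shall
should
can
could
may
might
must
of
in
on
at
by
for
with
about
against
between
into
through
during
before
after
above
below
to
from
up
down
out
off
over
under
again
further
here
there
all
any
both
each
few
more
most
other
some
such
no
not
only
own
same
too
very
s
t
just
now
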