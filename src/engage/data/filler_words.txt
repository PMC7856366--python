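# Filler vocabulary for synthetic statements. Filtered again at load time
# against the default lexicons; the generator additionally validates against
# any user-supplied lexicon so filler can never form a lexicon phrase.
the
of
and
to
in
we
our
for
that
with
on
as
by
this
be
have
has
are
is
it
from
at
their
will
which
all
its
was
were
not
but
also
they
can
must
more
these
international
united
nations
countries
country
world
people
government
states
development
support
peace
security
cooperation
efforts
community
region
regional
national
resolution
assembly
general
president
delegation
congratulate
session
progress
commitment
future
continue
work
important
new
years
today
many
need
such
through
other
between
those
made
make
process
peoples
hope
respect
rights
human
dialogue
organization
member
council
charter
reform
agenda
sustainable
goals
partnership
economy
trade
investment
institutions
stability
conflict
reconciliation
solidarity
prosperity
dignity
sovereignty
territorial
integrity
principles
multilateral
negotiations
agreement
implementation
framework
challenges
opportunities
responsibility
shared
common
believe
remain
committed
towards
address
ensure
strengthen
promote
achieve
together
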